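"""Rooted bifurcating phylogenetic trees with branch lengths in coalescent units.

Branch lengths throughout the package are measured in coalescent units
(multiples of 2N generations, where N is the reference population size).
The Newick dialect is strict: rooted, bifurcating, branch lengths mandatory
on every terminal and internal branch, no support values, trailing semicolon.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

__all__ = [
    "Node",
    "PhyloTree",
    "SpeciesTree",
    "GeneTree",
    "NewickError",
    "parse_newick",
    "write_newick",
    "root_to_tip_depths",
    "clades",
    "topology_key",
    "fitch_score",
]

_LABEL_RE = re.compile(r"[A-Za-z0-9_.\-]+")


class NewickError(ValueError):
    """Malformed Newick input or tree-invariant violation."""


class Node:
    """A node of a rooted tree; tips carry a label, all non-root nodes a branch length."""

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.children: list[Node] = []
        self.parent: Node | None = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> None:
        child.parent = self
        self.children.append(child)


class PhyloTree:
    """Rooted bifurcating tree with unique tip labels and non-negative branch lengths.

    The root has no branch length; every other node has one.  Internal nodes
    have exactly two children.
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- traversal ---------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    @property
    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_tip]

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self.tips]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def _validate(self) -> None:
        labels = []
        for node in self.preorder():
            if node.is_tip:
                if node.label is None:
                    raise NewickError("tip without a label")
                if not _LABEL_RE.fullmatch(node.label):
                    raise NewickError(f"illegal tip label: {node.label!r}")
                labels.append(node.label)
            elif len(node.children) != 2:
                raise NewickError(
                    f"internal node with {len(node.children)} children; tree must be bifurcating"
                )
            if node is not self.root:
                if node.length is None:
                    raise NewickError("missing branch length")
                if node.length < 0:
                    raise NewickError(f"negative branch length: {node.length}")
        if len(set(labels)) != len(labels):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate tip labels: {dup}")

    # -- geometry ----------------------------------------------------------
    def depths(self) -> dict[Node, float]:
        """Root-to-node path lengths (root = 0)."""
        d: dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is not self.root:
                d[node] = d[node.parent] + node.length
        return d

    def height(self) -> float:
        """Maximum root-to-tip depth."""
        d = self.depths()
        return max(d[t] for t in self.tips)

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = root_to_tip_depths(self)
        vals = list(depths.values())
        return max(vals) - min(vals) <= tol

    def mrca_depths(self) -> dict[tuple[str, str], float]:
        """Depth of the most recent common ancestor for every tip pair (i < j by label)."""
        depths = self.depths()
        tipsets: dict[Node, frozenset[str]] = {}
        out: dict[tuple[str, str], float] = {}
        for node in self.postorder():
            if node.is_tip:
                tipsets[node] = frozenset([node.label])
            else:
                left, right = (tipsets[c] for c in node.children)
                tipsets[node] = left | right
                for a in left:
                    for b in right:
                        out[tuple(sorted((a, b)))] = depths[node]
        return out

    def __repr__(self) -> str:
        return f"PhyloTree({write_newick(self)!r})"


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick string with mandatory branch lengths.

    Raises
    ------
    NewickError
        On malformed input, duplicate tip labels, or a missing branch length.
    """
    s = text.strip()
    if not s.endswith(";"):
        raise NewickError("Newick string must end with ';'")
    s = s[:-1]
    pos = 0

    def parse_clade(is_root: bool) -> Node:
        nonlocal pos
        if pos < len(s) and s[pos] == "(":
            pos += 1
            node = Node()
            node.add_child(parse_clade(False))
            while pos < len(s) and s[pos] == ",":
                pos += 1
                node.add_child(parse_clade(False))
            if pos >= len(s) or s[pos] != ")":
                raise NewickError("unbalanced parentheses")
            pos += 1
        else:
            m = _LABEL_RE.match(s, pos)
            if not m:
                raise NewickError(f"expected tip label at position {pos}")
            node = Node(label=m.group())
            pos = m.end()
        if pos < len(s) and s[pos] == ":":
            pos += 1
            m = re.compile(r"[0-9eE+\-.]+").match(s, pos)
            if not m:
                raise NewickError(f"expected branch length at position {pos}")
            try:
                node.length = float(m.group())
            except ValueError as exc:
                raise NewickError(f"bad branch length {m.group()!r}") from exc
            pos = m.end()
        elif not is_root:
            raise NewickError("missing branch length (lengths are mandatory)")
        return node

    root = parse_clade(True)
    if pos != len(s):
        raise NewickError(f"trailing characters after position {pos}: {s[pos:]!r}")
    return PhyloTree(root)


def _format_length(x: float) -> str:
    return repr(x) if x != int(x) else str(int(x))


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree; parse_newick(write_newick(t)) reproduces topology and lengths."""

    def fmt(node: Node) -> str:
        if node.is_tip:
            body = node.label
        else:
            body = "(" + ",".join(fmt(c) for c in node.children) + ")"
        if node.length is not None:
            body += f":{_format_length(node.length)}"
        return body

    return fmt(tree.root) + ";"


# ---------------------------------------------------------------------------
# Topology utilities
# ---------------------------------------------------------------------------

def root_to_tip_depths(tree: PhyloTree) -> dict[str, float]:
    """Sum of branch lengths on the root-to-tip path, keyed by tip label."""
    depths = tree.depths()
    return {t.label: depths[t] for t in tree.tips}


def clades(tree: PhyloTree) -> set[frozenset[str]]:
    """Descendant tip-label set of every internal non-root node (one per internal branch)."""
    tipsets: dict[Node, frozenset[str]] = {}
    out: set[frozenset[str]] = set()
    for node in tree.postorder():
        if node.is_tip:
            tipsets[node] = frozenset([node.label])
        else:
            tipsets[node] = frozenset().union(*(tipsets[c] for c in node.children))
            if node is not tree.root:
                out.add(tipsets[node])
    return out


def topology_key(tree: PhyloTree) -> str:
    """Canonical label-sorted Newick without branch lengths.

    Two trees share a key iff they share a rooted topology; the key is
    invariant under child-order rotations.
    """

    def key(node: Node) -> str:
        if node.is_tip:
            return node.label
        return "(" + ",".join(sorted(key(c) for c in node.children)) + ")"

    return key(tree.root)


def fitch_score(tree: PhyloTree, states: dict[str, int]) -> int:
    """Minimum number of binary state changes on the tree (Fitch parsimony).

    Parameters
    ----------
    states
        Tip label -> state in {0, 1}; every tip must be present.
    """
    missing = set(tree.tip_labels) - set(states)
    if missing:
        raise ValueError(f"missing tip states for: {sorted(missing)}")
    score = 0
    sets: dict[Node, frozenset[int]] = {}
    for node in tree.postorder():
        if node.is_tip:
            sets[node] = frozenset([states[node.label]])
        else:
            left, right = (sets[c] for c in node.children)
            inter = left & right
            if inter:
                sets[node] = inter
            else:
                sets[node] = left | right
                score += 1
    return score


# ---------------------------------------------------------------------------
# Species and gene trees
# ---------------------------------------------------------------------------

@dataclass
class SpeciesTree:
    """A species phylogeny with per-branch population-size multipliers.

    Each branch's multiplier scales the local population size relative to the
    reference N (multiplier 1).  The root entry scales the ancestral
    population above the root, where remaining gene lineages coalesce.
    """

    tree: PhyloTree
    multipliers: dict[Node, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node, f in self.multipliers.items():
            if f <= 0:
                raise ValueError(f"population-size multiplier must be > 0, got {f}")

    def multiplier(self, node: Node) -> float:
        return self.multipliers.get(node, 1.0)

    def with_ancestral_multiplier(self, f: float) -> "SpeciesTree":
        """All ancestral (non-terminal) populations scaled by f; terminal branches keep 1."""
        if f <= 0:
            raise ValueError("multiplier must be > 0")
        mult = {n: f for n in self.tree.preorder() if not n.is_tip}
        return SpeciesTree(self.tree, mult)

    @classmethod
    def from_newick(cls, text: str) -> "SpeciesTree":
        return cls(parse_newick(text))

    @property
    def tip_labels(self) -> list[str]:
        return self.tree.tip_labels


@dataclass
class GeneTree:
    """A coalescent genealogy for one locus, one sampled lineage per species.

    Tip labels equal the species they were sampled from; node times (coalescent
    units before the present) are encoded in the branch lengths.
    """

    tree: PhyloTree
    species_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.species_map is None:
            self.species_map = {l: l for l in self.tree.tip_labels}
        if sorted(self.species_map) != sorted(self.tree.tip_labels):
            raise ValueError("species_map keys must be exactly the tip labels")
        if len(set(self.species_map.values())) != len(self.species_map):
            raise ValueError("species_map must be a bijection")

    def node_times(self) -> dict[Node, float]:
        """Time before the present of every node (tips at their sampled time)."""
        depths = self.tree.depths()
        h = self.tree.height()
        return {n: h - d for n, d in depths.items()}

    def topology_key(self) -> str:
        return topology_key(self.tree)


# Paper study fixtures: branch lengths in units of 2N generations.
THREE_TAXON_NEWICK = "((A:1,B:1):4,C:5);"
FIVE_TAXON_NEWICK = "((((A:1,B:1):4,C:5):4,D:9):4,E:13);"


def three_taxon_tree() -> SpeciesTree:
    """The ((A:1,B:1):4,C:5) study tree."""
    return SpeciesTree.from_newick(THREE_TAXON_NEWICK)


def five_taxon_tree() -> SpeciesTree:
    """The ((((A:1,B:1):4,C:5):4,D:9):4,E:13) study tree."""
    return SpeciesTree.from_newick(FIVE_TAXON_NEWICK)
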
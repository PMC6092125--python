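"""Threshold (liability) traits: discretization and congruence classification.

A threshold trait is a binary character determined by whether an underlying
continuous liability exceeds a cutoff.  Here the simulated quantitative trait
values serve as liabilities; the cutoff for an ILS condition is one sample
standard deviation above the mean of all liabilities (all species, all
replicates) of that condition, so that conditions with more discordance --
and hence larger liability variances -- get proportionally higher cutoffs.

A replicate's 'trait pattern' is the vector of 0/1 states at the tips in
species-tree tip order.  A pattern is *uninformative* when fewer than two tips
carry either state; *congruent* when the set of '1' tips is exactly the
descendant clade of an internal species-tree branch (a single 0->1 gain, root
state 0); *incongruent* otherwise (homoplasy or hemiplasy required).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .msc import TraitDataset
from .trees import SpeciesTree, clades

__all__ = [
    "ThresholdSpec",
    "PatternTable",
    "compute_threshold",
    "discretize",
    "classify_pattern",
    "incongruence_frequency",
]

CONGRUENT = "congruent"
INCONGRUENT = "incongruent"
UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class ThresholdSpec:
    """Pooled liability mean/SD and the cutoff one SD above the mean."""

    mean: float
    sd: float
    scope: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def cutoff(self) -> float:
        return self.mean + self.sd


def compute_threshold(liabilities, scope: str = "") -> ThresholdSpec:
    """Cutoff = sample mean + 1 sample SD (ddof=1) of the pooled liabilities.

    ``liabilities`` may be a TraitDataset (pooled over all species and
    replicates) or any array-like of values; needs at least 2 values.
    """
    if isinstance(liabilities, TraitDataset):
        vals = liabilities.values.ravel()
    else:
        vals = np.asarray(liabilities, dtype=float).ravel()
    if vals.size < 2:
        raise ValueError("need at least 2 liability values")
    return ThresholdSpec(mean=float(vals.mean()), sd=float(vals.std(ddof=1)), scope=scope)


@dataclass
class PatternTable:
    """Per-replicate binary patterns with counts and congruence classes."""

    species: list[str]
    patterns: list[str]
    spec: ThresholdSpec
    counts: Counter = field(default_factory=Counter)
    classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.counts:
            self.counts = Counter(self.patterns)

    @property
    def n_replicates(self) -> int:
        return len(self.patterns)

    def classify(self, tree: SpeciesTree, allow_complement: bool = False) -> "PatternTable":
        """Fill the class label of every counted pattern; returns self."""
        if tree.tip_labels != self.species:
            raise ValueError("tree tip order does not match the pattern table")
        for pat in self.counts:
            self.classes[pat] = classify_pattern(tree, pat, allow_complement)
        return self

    def class_counts(self) -> Counter:
        if not self.classes:
            raise ValueError("patterns not classified; call classify(tree) first")
        out: Counter = Counter()
        for pat, n in self.counts.items():
            out[self.classes[pat]] += n
        return out


def discretize(
    dataset: TraitDataset, spec: ThresholdSpec, tree: SpeciesTree | None = None
) -> PatternTable:
    """Code liabilities as 0/1 against the cutoff (strictly above -> 1, ties -> 0).

    If a tree is given the patterns are classified immediately.
    """
    bits = (dataset.values > spec.cutoff).astype(int)
    patterns = ["".join(map(str, row)) for row in bits]
    table = PatternTable(species=list(dataset.species), patterns=patterns, spec=spec)
    if tree is not None:
        table.classify(tree)
    return table


def classify_pattern(
    tree: SpeciesTree, pattern, allow_complement: bool = False
) -> str:
    """Classify a binary tip pattern against the species tree.

    ``pattern`` is a string like "11000" or a 0/1 sequence, ordered by the
    species tree's tip order.  With ``allow_complement`` the '0' tips forming a
    clade also counts as congruent (single change with free root state); off by
    default, matching a single derived gain from ancestral state 0.
    """
    labels = tree.tip_labels
    states = [int(b) for b in pattern]
    if len(states) != len(labels):
        raise ValueError(f"pattern length {len(states)} != {len(labels)} tips")
    if any(s not in (0, 1) for s in states):
        raise ValueError("pattern states must be 0 or 1")
    ones = frozenset(l for l, s in zip(labels, states) if s == 1)
    zeros = frozenset(labels) - ones
    if len(ones) < 2 or len(zeros) < 2:
        return UNINFORMATIVE
    tree_clades = clades(tree.tree)
    if ones in tree_clades:
        return CONGRUENT
    if allow_complement and zeros in tree_clades:
        return CONGRUENT
    return INCONGRUENT


def incongruence_frequency(table: PatternTable, two_one_only: bool = True) -> float | None:
    """Incongruent fraction of informative patterns: incongruent / (congruent + incongruent).

    With ``two_one_only`` (default) only patterns with exactly two '1' states
    (and the rest '0') are tabulated.  Returns None when no qualifying
    informative pattern was observed.
    """
    if not table.classes:
        raise ValueError("patterns not classified; call classify(tree) first")
    n_con = n_inc = 0
    for pat, n in table.counts.items():
        if two_one_only and pat.count("1") != 2:
            continue
        cls = table.classes[pat]
        if cls == CONGRUENT:
            n_con += n
        elif cls == INCONGRUENT:
            n_inc += n
    denom = n_con + n_inc
    if denom == 0:
        return None
    return n_inc / denom
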
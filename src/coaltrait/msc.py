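"""Gene-tree and quantitative-trait simulation under the multispecies coalescent.

A trait is controlled by L unlinked loci.  For each locus a genealogy is drawn
under the multispecies coalescent along the species tree (one haploid lineage
sampled per species); mutations fall on gene-tree branches as a Poisson process
with rate theta/2 per coalescent unit; each mutation's effect is drawn from
Normal(0, sigma_M^2 / L) and is inherited by every species descending from the
mutated branch.  A species' trait value is the sum of inherited effects across
all loci (the ancestral state contributes 0).

Incomplete lineage sorting is controlled by multiplying ancestral population
sizes by a factor f >= 1 (branch lengths held constant), which rescales the
coalescence rate inside ancestral populations by 1/f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expectations import MutationModel, calibrate_multiplier, calibrate_multiplier_mc
from .trees import GeneTree, Node, PhyloTree, SpeciesTree, topology_key

__all__ = [
    "ILSCondition",
    "TraitDataset",
    "simulate_gene_tree",
    "simulate_locus_contributions",
    "simulate_trait_dataset",
    "simulate_discordance_fraction",
    "empirical_discordance",
    "summary_moments",
    "Moments",
]


# ---------------------------------------------------------------------------
# Compact species-tree tables for the hot simulation path
# ---------------------------------------------------------------------------

class _SpeciesTables:
    """Postorder species-tree tables: heights, multipliers, child pools."""

    __slots__ = ("labels", "n_tips", "entries", "key")

    def __init__(self, stree: SpeciesTree):
        ptree = stree.tree
        self.labels = ptree.tip_labels
        self.n_tips = len(self.labels)
        self.key = topology_key(ptree)
        depths = ptree.depths()
        h_root = max(depths[t] for t in ptree.tips)
        order = list(ptree.postorder())
        index = {node: i for i, node in enumerate(order)}
        self.entries = []
        tip_id = {lab: i for i, lab in enumerate(self.labels)}
        for node in order:
            height = h_root - depths[node]
            top = math.inf if node is ptree.root else h_root - depths[node.parent]
            self.entries.append(
                (
                    height,
                    top,
                    stree.multiplier(node),
                    [index[c] for c in node.children],
                    tip_id[node.label] if node.is_tip else -1,
                )
            )


_TABLE_CACHE: dict[int, tuple[SpeciesTree, _SpeciesTables]] = {}


def _tables(stree: SpeciesTree) -> _SpeciesTables:
    cached = _TABLE_CACHE.get(id(stree))
    if cached is not None and cached[0] is stree:
        return cached[1]
    tab = _SpeciesTables(stree)
    _TABLE_CACHE[id(stree)] = (stree, tab)
    if len(_TABLE_CACHE) > 64:
        _TABLE_CACHE.pop(next(iter(_TABLE_CACHE)))
    return tab


def _simulate_genealogy(
    tab: _SpeciesTables, rng: np.random.Generator
) -> tuple[list[float], list[tuple[int, int]]]:
    """One MSC genealogy.  Returns (node times, children pairs for internal nodes).

    Node ids: 0..n_tips-1 are the sampled lineages (one per species, in tip
    order); internal node k has id n_tips + k and was created after its
    children.  Within a species-tree branch with k lineages and multiplier f
    the waiting time to the next coalescence is Exp(k(k-1)/2 / f).
    """
    n = tab.n_tips
    times: list[float] = [0.0] * n
    children: list[tuple[int, int]] = []
    next_id = n
    pools: list[list[int] | None] = [None] * len(tab.entries)
    for i, (height, top, mult, child_idx, tip_id) in enumerate(tab.entries):
        if tip_id >= 0:
            pool = [tip_id]
            times[tip_id] = height
        else:
            pool = pools[child_idx[0]] + pools[child_idx[1]]
            pools[child_idx[0]] = pools[child_idx[1]] = None
        t = height
        k = len(pool)
        while k >= 2:
            t += rng.exponential(mult / (0.5 * k * (k - 1)))
            if t >= top:
                break
            i1 = int(rng.integers(k))
            i2 = int(rng.integers(k - 1))
            if i2 >= i1:
                i2 += 1
            if i1 < i2:
                i1, i2 = i2, i1
            a = pool.pop(i1)
            b = pool.pop(i2)
            children.append((a, b))
            times.append(t)
            pool.append(next_id)
            next_id += 1
            k -= 1
        pools[i] = pool
    return times, children


def _genealogy_key(tab: _SpeciesTables, children: list[tuple[int, int]]) -> str:
    keys = list(tab.labels)
    for a, b in children:
        ka, kb = keys[a], keys[b]
        keys.append(f"({ka},{kb})" if ka < kb else f"({kb},{ka})")
    return keys[-1]


def _genealogy_contributions(
    tab: _SpeciesTables,
    times: list[float],
    children: list[tuple[int, int]],
    theta: float,
    effect_var: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-species trait contribution of one locus (compound-Poisson mutation model)."""
    n = tab.n_tips
    total = len(times)
    masks = [1 << i for i in range(n)]
    parent_time = [0.0] * (total - 1)
    for k, (a, b) in enumerate(children):
        masks.append(masks[a] | masks[b])
        t = times[n + k]
        parent_time[a] = t
        parent_time[b] = t
    # branch lengths for all non-root nodes
    lengths = np.array([parent_time[i] - times[i] for i in range(total - 1)])
    counts = rng.poisson(lengths * (0.5 * theta))
    contrib = np.zeros(n)
    sd = math.sqrt(effect_var)
    for node_id in np.nonzero(counts)[0]:
        s = rng.normal(0.0, sd * math.sqrt(counts[node_id]))
        m = masks[node_id]
        i = 0
        while m:
            if m & 1:
                contrib[i] += s
            m >>= 1
            i += 1
    return contrib


# ---------------------------------------------------------------------------
# Public simulation API
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ILSCondition:
    """An incomplete-lineage-sorting condition: a target gene-tree discordance
    fraction and the ancestral population-size multiplier that achieves it.

    The multiplier applies to all non-terminal (ancestral) populations,
    including the root; terminal-branch populations keep multiplier 1.
    """

    label: str
    target_discordance: float
    multiplier: float

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("ancestral multiplier must be >= 1")
        if not 0 <= self.target_discordance < 1:
            raise ValueError("target discordance must be in [0, 1)")

    def apply(self, tree: SpeciesTree) -> SpeciesTree:
        return tree.with_ancestral_multiplier(self.multiplier)

    @classmethod
    def calibrate(
        cls,
        tree: SpeciesTree,
        target_discordance: float,
        n_sims: int = 10_000,
        seed: int | np.random.Generator = 0,
        label: str | None = None,
    ) -> "ILSCondition":
        """Calibrate the multiplier for a target discordance fraction.

        For a 3-taxon tree the analytic inversion of (2/3)e^(-x0/f) is used;
        otherwise Monte-Carlo bisection on the simulated discordance fraction.
        """
        if label is None:
            label = f"disc{target_discordance:g}"
        internal = [
            n for n in tree.tree.preorder() if not n.is_tip and n is not tree.tree.root
        ]
        if tree.tree.n_tips == 3 and len(internal) == 1:
            f = max(1.0, calibrate_multiplier(internal[0].length, target_discordance))
        else:
            f = calibrate_multiplier_mc(tree, target_discordance, n_sims, seed)
        return cls(label=label, target_discordance=target_discordance, multiplier=f)


def simulate_gene_tree(
    tree: SpeciesTree,
    condition: ILSCondition | None = None,
    rng: np.random.Generator | int | None = None,
) -> GeneTree:
    """Draw one gene tree under the multispecies coalescent (one lineage per species)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    stree = condition.apply(tree) if condition is not None else tree
    tab = _tables(stree)
    times, children = _simulate_genealogy(tab, rng)
    n = tab.n_tips
    nodes = [Node(label=lab) for lab in tab.labels]
    for k, (a, b) in enumerate(children):
        parent = Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes.append(parent)
        for child_id in (a, b):
            nodes[child_id].length = times[n + k] - times[child_id]
    return GeneTree(PhyloTree(nodes[-1]))


def simulate_locus_contributions(
    gtree: GeneTree,
    model: MutationModel,
    rng: np.random.Generator | int | None = None,
    *,
    effect_var: float | None = None,
) -> dict[str, float]:
    """Per-species trait contribution of a single locus on a given genealogy.

    Mutation counts on a branch of length ell are Poisson(ell * theta / 2);
    mutation effects are iid Normal(0, effect_var) (default: model.sigma_m2,
    unscaled) and are inherited by every descendant species of the branch.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if effect_var is None:
        effect_var = model.sigma_m2
    ptree = gtree.tree
    times = gtree.node_times()
    contrib = {lab: 0.0 for lab in ptree.tip_labels}
    tipsets: dict[Node, list[str]] = {}
    for node in ptree.postorder():
        if node.is_tip:
            tipsets[node] = [node.label]
        else:
            tipsets[node] = tipsets[node.children[0]] + tipsets[node.children[1]]
        if node is ptree.root:
            continue
        n_mut = rng.poisson(node.length * 0.5 * model.theta)
        if n_mut and effect_var > 0:
            s = rng.normal(0.0, math.sqrt(effect_var * n_mut))
            for lab in tipsets[node]:
                contrib[lab] += s
    return contrib


@dataclass
class TraitDataset:
    """Replicate-by-species matrix of simulated trait values plus provenance.

    ``values[r, s]`` is the trait value of species ``species[s]`` in replicate
    ``r``.  ``replicate_seeds`` reproduce each row bit-for-bit; ``topologies``
    (optional) holds the per-locus gene-tree topology keys of each replicate.
    """

    condition: ILSCondition
    n_loci: int
    species: list[str]
    values: np.ndarray
    seed: int | None = None
    replicate_seeds: list[int] = field(default_factory=list)
    topologies: list[list[str]] | None = None

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with columns replicate, species, value."""
        n_rep, n_sp = self.values.shape
        return pd.DataFrame(
            {
                "replicate": np.repeat(np.arange(n_rep), n_sp),
                "species": np.tile(self.species, n_rep),
                "value": self.values.ravel(),
            }
        )

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @staticmethod
    def matrix_from_table(df: pd.DataFrame) -> tuple[list[str], np.ndarray]:
        """Pivot a long-format (replicate, species, value) table to a matrix."""
        wide = df.pivot(index="replicate", columns="species", values="value")
        return list(wide.columns), wide.to_numpy()


def simulate_trait_dataset(
    tree: SpeciesTree,
    condition: ILSCondition,
    n_loci: int,
    model: MutationModel | None = None,
    n_replicates: int = 1000,
    seed: int = 0,
    *,
    record_topologies: bool = False,
) -> TraitDataset:
    """Simulate a replicate-by-species trait matrix under the MSC.

    Each replicate draws ``n_loci`` independent genealogies and sums their
    per-species contributions; the per-mutation effect variance is
    ``model.sigma_m2 / n_loci`` (infinitesimal scaling, so the expected trait
    variance does not depend on the number of loci).
    """
    if n_loci < 1 or n_replicates < 1:
        raise ValueError("n_loci and n_replicates must be >= 1")
    if model is None:
        model = MutationModel()
    stree = condition.apply(tree)
    tab = _tables(stree)
    effect_var = model.sigma_m2 / n_loci
    rep_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n_replicates)]
    values = np.zeros((n_replicates, tab.n_tips))
    topologies: list[list[str]] | None = [] if record_topologies else None
    for r, rs in enumerate(rep_seeds):
        # separate streams: genealogies are independent of the mutation process,
        # so topologies are reproducible regardless of theta / effect variance
        gene_rng, mut_rng = map(np.random.default_rng, np.random.SeedSequence(rs).spawn(2))
        row = np.zeros(tab.n_tips)
        keys: list[str] = []
        for _ in range(n_loci):
            times, children = _simulate_genealogy(tab, gene_rng)
            row += _genealogy_contributions(
                tab, times, children, model.theta, effect_var, mut_rng
            )
            if record_topologies:
                keys.append(_genealogy_key(tab, children))
        values[r] = row
        if record_topologies:
            topologies.append(keys)
    return TraitDataset(
        condition=condition,
        n_loci=n_loci,
        species=list(tab.labels),
        values=values,
        seed=seed,
        replicate_seeds=rep_seeds,
        topologies=topologies,
    )


def simulate_discordance_fraction(
    tree: SpeciesTree, n_sims: int, rng: np.random.Generator | int | None = None
) -> float:
    """Fraction of n_sims simulated gene trees topologically discordant with the species tree."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    tab = _tables(tree)
    disc = 0
    for _ in range(n_sims):
        _, children = _simulate_genealogy(tab, rng)
        if _genealogy_key(tab, children) != tab.key:
            disc += 1
    return disc / n_sims


def empirical_discordance(dataset: TraitDataset, tree: SpeciesTree) -> float:
    """Fraction of loci (pooled over replicates) whose genealogy is discordant."""
    if dataset.topologies is None:
        raise ValueError("dataset was simulated without record_topologies=True")
    skey = topology_key(tree.tree)
    total = sum(len(ks) for ks in dataset.topologies)
    disc = sum(k != skey for ks in dataset.topologies for k in ks)
    return disc / total


@dataclass
class Moments:
    """Across-replicate sample moments of a trait dataset."""

    species: list[str]
    cov: np.ndarray  # sample covariance matrix, denominator n-1

    def variance(self, sp: str) -> float:
        i = self.species.index(sp)
        return float(self.cov[i, i])

    def covariance(self, a: str, b: str) -> float:
        i, j = self.species.index(a), self.species.index(b)
        return float(self.cov[i, j])

    def normalized_by(self, sp: str | None = None) -> np.ndarray:
        """Covariance matrix divided by Var(sp) (default: the first species)."""
        sp = sp or self.species[0]
        v = self.variance(sp)
        if v <= 0:
            raise ValueError(f"Var({sp}) must be > 0 to normalize")
        return self.cov / v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.cov, index=self.species, columns=self.species)


def summary_moments(dataset: TraitDataset) -> Moments:
    """Sample variances/covariances of trait values across replicates (ddof=1)."""
    if dataset.n_replicates < 2:
        raise ValueError("need at least 2 replicates to compute moments")
    cov = np.cov(dataset.values, rowvar=False, ddof=1)
    return Moments(species=list(dataset.species), cov=np.atleast_2d(cov))
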
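"""Closed-form trait expectations under Brownian motion and the multispecies coalescent.

All times are in coalescent units (2N generations).  The coalescent
expectations carry the prefactor 2N mu sigma_M^2, which in these units equals
(theta/2) * sigma_M^2 with theta = 4N mu the per-locus population mutation
parameter; exposing theta removes N and mu as separate free parameters and
matches how the simulator places mutations.

For the three-species tree ((A,B),C) with internal branch x = t/2N and
terminal branch t_e, the per-locus expectations are

    Var[A] = Var[B] = pref * [t_e + (1-e^-x)(x+1) + e^-x (x + 1 + 1/3)]
    Var[C]          = pref * [t_e + (1-e^-x)      + e^-x (1 + 1/3)]      (x-terms dropped)
    Cov[A,B]        = pref * [(1-e^-x)(1 + x - (1 - x/(e^x - 1))) + e^-x/3]
    Cov[A,C]=Cov[B,C]= pref * e^-x / 3

where pref = (theta/2) sigma_M^2.  The sister covariance simplifies to
pref * (x + e^-x/3); the x = 0 singularity of the printed form is removable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .trees import Node, PhyloTree, SpeciesTree

__all__ = [
    "MutationModel",
    "VCVMatrix",
    "bm_vcv",
    "coal_var",
    "coal_cov_sisters",
    "coal_cov_nonsisters",
    "coal_vcv_3taxon",
    "topology_probs_3taxon",
    "prob_no_coalescence",
    "count_rooted_topologies",
    "calibrate_multiplier",
    "calibrate_multiplier_mc",
]


@dataclass(frozen=True)
class MutationModel:
    """Per-locus mutational model.

    Parameters
    ----------
    theta
        Population mutation parameter 4*N*mu per locus (> 0).
    sigma_m2
        Variance of the Gaussian per-mutation effect distribution (> 0).
    n_loci
        Number of loci L underlying the trait (>= 1).  Under the default
        infinitesimal scaling each locus uses effect variance sigma_m2 / L so
        the total trait variance is constant in L.
    """

    theta: float = 4.0
    sigma_m2: float = 1.0
    n_loci: int = 1

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.sigma_m2 < 0:
            raise ValueError("sigma_m2 must be >= 0")
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")

    @property
    def prefactor(self) -> float:
        """2*N*mu*sigma_M^2 in coalescent time units: (theta/2) * sigma_m2."""
        return 0.5 * self.theta * self.sigma_m2

    @property
    def per_locus_effect_var(self) -> float:
        """Per-mutation effect variance after infinitesimal scaling by L."""
        return self.sigma_m2 / self.n_loci


@dataclass
class VCVMatrix:
    """Labelled symmetric PSD matrix of trait variances and covariances."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("matrix must be symmetric")
        eigmin = np.linalg.eigvalsh(self.values).min() if n else 0.0
        if eigmin < -1e-9 * max(1.0, abs(self.values).max()):
            raise ValueError(f"matrix not PSD (min eigenvalue {eigmin})")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = (self.labels.index(p) for p in pair)
        return float(self.values[i, j])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# Brownian motion
# ---------------------------------------------------------------------------

def bm_vcv(tree: SpeciesTree | PhyloTree, sigma2: float = 1.0) -> VCVMatrix:
    """Brownian-motion variance-covariance matrix V = sigma^2 * T.

    Diagonal entries are sigma^2 times the root-to-tip depth; the (i, j) entry
    is sigma^2 times the depth of the most recent common ancestor of i and j.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    ptree = tree.tree if isinstance(tree, SpeciesTree) else tree
    labels = ptree.tip_labels
    depths = ptree.depths()
    tipd = {t.label: depths[t] for t in ptree.tips}
    mrca = ptree.mrca_depths()
    n = len(labels)
    T = np.zeros((n, n))
    for i, a in enumerate(labels):
        T[i, i] = tipd[a]
        for j in range(i + 1, n):
            b = labels[j]
            T[i, j] = T[j, i] = mrca[tuple(sorted((a, b)))]
    return VCVMatrix(labels, sigma2 * T)


# ---------------------------------------------------------------------------
# Coalescent closed forms (three-species tree)
# ---------------------------------------------------------------------------

def coal_var(
    x: float,
    t_e: float,
    model: MutationModel | None = None,
    outgroup: bool = False,
) -> float:
    """Expected per-locus trait variance within a species under the coalescent.

    Parameters
    ----------
    x
        Internal branch length in local coalescent units (t / 2N, scaled by the
        ancestral population multiplier).
    t_e
        Terminal branch length leading to the species, in coalescent units.
    outgroup
        For the outgroup C the internal-branch terms are dropped from the path
        length component (C's lineage does not traverse the internal branch).
    """
    if x < 0 or t_e < 0:
        raise ValueError("branch lengths must be >= 0")
    pref = model.prefactor if model is not None else 1.0
    p_no = math.exp(-x)
    if outgroup:
        bracket = t_e + (1.0 - p_no) * 1.0 + p_no * (1.0 + 1.0 / 3.0)
    else:
        bracket = t_e + (1.0 - p_no) * (x + 1.0) + p_no * (x + 1.0 + 1.0 / 3.0)
    return pref * bracket


def coal_cov_sisters(x: float, model: MutationModel | None = None) -> float:
    """Expected per-locus trait covariance between the sister species A and B.

    Evaluates the printed form
    pref * [(1-e^-x)(1 + x - (1 - x/(e^x - 1))) + e^-x/3];
    the removable singularity at x = 0 is handled by its continuity limit 1/3.
    Algebraically the whole expression equals pref * (x + e^-x/3).
    """
    if x < 0:
        raise ValueError("x must be >= 0")
    pref = model.prefactor if model is not None else 1.0
    p_no = math.exp(-x)
    if x < 1e-12:
        return pref * (x + p_no / 3.0)  # continuity limit of the garbled middle term
    middle = 1.0 + x - (1.0 - x / math.expm1(x))
    return pref * ((1.0 - p_no) * middle + p_no / 3.0)


def coal_cov_nonsisters(x: float, model: MutationModel | None = None) -> float:
    """Expected per-locus covariance between a sister species and the outgroup:
    pref * (1/3) e^-x.  Nonzero only through discordant genealogies (hemiplasy)."""
    if x < 0:
        raise ValueError("x must be >= 0")
    pref = model.prefactor if model is not None else 1.0
    return pref * math.exp(-x) / 3.0


def coal_vcv_3taxon(tree: SpeciesTree, model: MutationModel | None = None) -> VCVMatrix:
    """Assemble the per-locus coalescent expectation matrix for a 3-taxon tree ((A,B),C).

    The ancestral population-size multiplier f rescales the coalescent process
    inside ancestral populations: the effective internal branch is x = t / f,
    and every waiting-time term accrues path length f times faster in the
    reference time unit.  Each entry is therefore f times the closed form
    evaluated at x, except the terminal-branch contribution t_e, which is
    spent in unscaled populations:

        Var      = pref * (t_e + f * [x + 1 + e^-x/3])      (sisters)
        Var_C    = pref * (t_e + f * [1 + e^-x/3])          (outgroup)
        Cov(A,B) = pref * f * (x + e^-x/3) = pref * (t + f e^-x/3)
        Cov(A,C) = pref * f * e^-x / 3

    With f = 1 these reduce to the plain closed forms.  Both trait variances
    and covariances grow with f (the deep-coalescence effect), while the gap
    Cov(A,B) - Cov(A,C) stays pinned at pref * t.
    """
    ptree = tree.tree
    if ptree.n_tips != 3:
        raise ValueError("coal_vcv_3taxon requires exactly 3 tips")
    internal = [n for n in ptree.preorder() if not n.is_tip and n is not ptree.root]
    if len(internal) != 1:
        raise ValueError("tree must have topology ((A,B),C)")
    inode = internal[0]
    f = tree.multiplier(inode)
    if tree.multiplier(ptree.root) != f:
        raise ValueError("closed forms assume one shared ancestral multiplier")
    x = inode.length / f
    sisters = [c.label for c in inode.children]
    (out,) = [l for l in ptree.tip_labels if l not in sisters]
    tipd = {t.label: t.length for t in ptree.tips}
    pref = model.prefactor if model is not None else 1.0

    labels = ptree.tip_labels
    n = 3
    V = np.zeros((n, n))
    for i, a in enumerate(labels):
        V[i, i] = pref * tipd[a] + f * coal_var(x, 0.0, model, outgroup=(a == out))
        for j in range(i + 1, n):
            b = labels[j]
            if out in (a, b):
                V[i, j] = V[j, i] = f * coal_cov_nonsisters(x, model)
            else:
                V[i, j] = V[j, i] = f * coal_cov_sisters(x, model)
    return VCVMatrix(labels, V)


# ---------------------------------------------------------------------------
# Gene-tree topology probabilities and calibration
# ---------------------------------------------------------------------------

def prob_no_coalescence(x: float) -> float:
    """Probability two lineages fail to coalesce within a branch of length x: e^-x."""
    if x < 0:
        raise ValueError("x must be >= 0")
    return math.exp(-x)


def topology_probs_3taxon(x: float) -> tuple[float, float, float]:
    """Gene-tree topology probabilities for three species with internal branch x.

    Returns (concordant, discordant_1, discordant_2) =
    (1 - (2/3) e^-x, (1/3) e^-x, (1/3) e^-x).
    """
    p_no = prob_no_coalescence(x)
    return (1.0 - 2.0 * p_no / 3.0, p_no / 3.0, p_no / 3.0)


def count_rooted_topologies(n: int) -> int:
    """Number of rooted bifurcating labelled topologies on n tips: (2n-3)!!."""
    if n < 2:
        raise ValueError("n must be >= 2")
    out = 1
    for k in range(3, 2 * n - 2, 2):
        out *= k
    return out


def calibrate_multiplier(x0: float, target_discordance: float) -> float:
    """Ancestral population-size multiplier achieving a target 3-taxon discordance.

    Solves (2/3) exp(-x0 / f) = target analytically:
    f = x0 / (-ln(3 * target / 2)).  By convention target 0 maps to f = 1 (the
    unscaled tree, whose residual discordance (2/3)e^-x0 is the attainable floor).
    """
    if x0 <= 0:
        raise ValueError("x0 must be > 0")
    if not 0 <= target_discordance < 2.0 / 3.0:
        raise ValueError("target discordance must be in [0, 2/3)")
    if target_discordance == 0:
        return 1.0
    return x0 / (-math.log(1.5 * target_discordance))


def calibrate_multiplier_mc(
    tree: SpeciesTree,
    target_discordance: float,
    n_sims: int = 10_000,
    rng_seed: int | np.random.Generator = 0,
    *,
    max_iter: int = 40,
    f_max: float = 1e6,
) -> float:
    """Monte-Carlo bisection for the multiplier achieving a target discordance fraction.

    The objective is the simulated fraction of gene trees whose topology differs
    from the species tree's over n_sims multispecies-coalescent draws; bisection
    on f in [1, f_max] stops when the objective is within 2 Monte-Carlo standard
    errors of the target, or after max_iter iterations.  Discordance is
    monotone increasing in f, so bisection on a noisy but consistent objective
    converges to MC accuracy.
    """
    from .msc import simulate_discordance_fraction

    if not 0 <= target_discordance < 1:
        raise ValueError("target discordance must be in [0, 1)")
    if target_discordance == 0:
        return 1.0
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )

    def objective(f: float) -> float:
        return simulate_discordance_fraction(tree.with_ancestral_multiplier(f), n_sims, rng)

    se = math.sqrt(max(target_discordance * (1 - target_discordance), 1e-4) / n_sims)
    lo, hi = 1.0, f_max
    d_lo = objective(lo)
    if d_lo >= target_discordance:
        return lo  # baseline tree already at/above the target
    d_hi = objective(hi)
    if d_hi < target_discordance - 2 * se:
        raise ValueError(
            f"target discordance {target_discordance} unreachable "
            f"(max observed {d_hi:.4f} at multiplier {f_max})"
        )
    f = hi
    for _ in range(max_iter):
        f = math.sqrt(lo * hi)  # geometric bisection: f spans orders of magnitude
        d = objective(f)
        if abs(d - target_discordance) <= 2 * se:
            return f
        if d < target_discordance:
            lo = f
        else:
            hi = f
    return f
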
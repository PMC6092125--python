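"""Maximum-likelihood Brownian-motion and Pagel's lambda fits on a fixed species tree.

The model: one trait observation per species (the species mean), multivariate
normal with mean ``root_state * 1`` and covariance ``sigma2 * T_lambda``, where
T is the shared-path-length matrix of the species tree and T_lambda has its
off-diagonal entries multiplied by lambda in [0, 1] (lambda = 1 is pure BM on
the tree, lambda = 0 a star phylogeny).

For fixed lambda the root state and rate have closed-form generalized
least-squares solutions

    m_hat      = (1' R^-1 z) / (1' R^-1 1)
    sigma2_hat = (z - m_hat 1)' R^-1 (z - m_hat 1) / n      (ML denominator n)

with R = T_lambda; lambda itself is profiled by bounded scalar optimization.
Estimation is ML, not REML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .expectations import VCVMatrix, bm_vcv
from .trees import SpeciesTree

__all__ = [
    "BrownianMotionModel",
    "BMResults",
    "lambda_transform",
    "bm_loglik",
    "fit_sigma2",
    "fit_lambda_sigma2",
    "simulate_bm_traits",
]

_LOG_2PI = math.log(2.0 * math.pi)


def lambda_transform(V: VCVMatrix, lam: float) -> VCVMatrix:
    """Pagel's lambda transform: off-diagonal entries scaled by lam, diagonal kept.

    For an ultrametric-tree covariance this interpolates between the tree
    (lam = 1) and a star phylogeny (lam = 0) and stays positive semidefinite.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    out = V.values * lam
    np.fill_diagonal(out, np.diag(V.values))
    return VCVMatrix(list(V.labels), out)


def _chol(R: np.ndarray):
    try:
        return cho_factor(R, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"covariance matrix not positive definite (condition ~ {np.linalg.cond(R):.2e})"
        ) from exc


def bm_loglik(
    tree: SpeciesTree,
    traits: Mapping[str, float],
    sigma2: float,
    lam: float = 1.0,
    root_state: float = 0.0,
) -> float:
    """Log-likelihood of traits under BM(sigma2) with Pagel's lambda on the tree."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    model = BrownianMotionModel(tree, traits)
    return model.loglik(sigma2=sigma2, lam=lam, root_state=root_state)


class BrownianMotionModel:
    """Brownian-motion trait model on a fixed species tree.

    Parameters
    ----------
    tree
        The species tree (branch lengths in coalescent units).
    traits
        Mapping or Series of one trait value per tip label.
    """

    def __init__(self, tree: SpeciesTree, traits: Mapping[str, float] | pd.Series):
        self.tree = tree
        labels = tree.tip_labels
        missing = [l for l in labels if l not in traits]
        if missing:
            raise ValueError(f"traits missing for species: {missing}")
        self.labels = labels
        self.z = np.array([float(traits[l]) for l in labels])
        self.T = bm_vcv(tree, 1.0)
        self.nobs = len(labels)

    @classmethod
    def from_dataframe(
        cls, tree: SpeciesTree, df: pd.DataFrame, replicate: int | None = None
    ) -> "BrownianMotionModel":
        """Build from a long-format (replicate, species, value) table."""
        if replicate is not None:
            df = df[df["replicate"] == replicate]
        series = df.set_index("species")["value"]
        return cls(tree, series)

    # -- likelihood ----------------------------------------------------------
    def _R(self, lam: float) -> np.ndarray:
        if lam == 1.0:
            return self.T.values
        return lambda_transform(self.T, lam).values

    def loglik(self, sigma2: float, lam: float = 1.0, root_state: float = 0.0) -> float:
        """Exact multivariate-normal log-density at the given parameters."""
        if sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        R = self._R(lam)
        c = _chol(sigma2 * R)
        resid = self.z - root_state
        quad = resid @ cho_solve(c, resid)
        logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
        return -0.5 * (self.nobs * _LOG_2PI + logdet + quad)

    def _profile(self, lam: float) -> tuple[float, float, float]:
        """Closed-form (root_state, sigma2, loglik) at fixed lambda (ML)."""
        n = self.nobs
        R = self._R(lam)
        c = _chol(R)
        ones = np.ones(n)
        Ri1 = cho_solve(c, ones)
        m = float(ones @ cho_solve(c, self.z) / (ones @ Ri1))
        resid = self.z - m
        sigma2 = float(resid @ cho_solve(c, resid)) / n
        if sigma2 <= 0:
            return m, 0.0, math.inf
        logdet_R = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        ll = -0.5 * (n * _LOG_2PI + n * math.log(sigma2) + logdet_R + n)
        return m, sigma2, ll

    # -- fitting ---------------------------------------------------------------
    def fit(self, estimate_lambda: bool = False, xatol: float = 1e-8) -> "BMResults":
        """ML fit.  With ``estimate_lambda`` the profile over lambda in [0, 1]
        is maximized by bounded scalar optimization (boundaries checked
        explicitly); otherwise lambda is fixed at 1 (pure BM)."""
        if self.nobs < 3:
            raise ValueError("need at least 3 species")
        if not estimate_lambda:
            m, s2, ll = self._profile(1.0)
            return BMResults(
                model=self,
                root_state=m,
                sigma2=s2,
                lambda_=None,
                llf=ll,
                degenerate=(s2 == 0.0),
            )
        if self.nobs < 4:
            raise ValueError("lambda estimation needs at least 4 species")

        def neg(lam: float) -> float:
            return -self._profile(lam)[2]

        res = optimize.minimize_scalar(
            neg, bounds=(0.0, 1.0), method="bounded", options={"xatol": xatol}
        )
        candidates = [(0.0, -neg(0.0)), (1.0, -neg(1.0)), (float(res.x), -float(res.fun))]
        lam_hat, ll_hat = max(candidates, key=lambda p: p[1])
        flat = abs(candidates[0][1] - candidates[1][1]) < 1e-10 and abs(
            candidates[2][1] - candidates[1][1]
        ) < 1e-10
        m, s2, ll = self._profile(lam_hat)
        return BMResults(
            model=self,
            root_state=m,
            sigma2=s2,
            lambda_=lam_hat,
            llf=ll,
            degenerate=(s2 == 0.0),
            flat_profile=flat,
        )


@dataclass
class BMResults:
    """ML estimates of a Brownian-motion (optionally lambda-transformed) fit."""

    model: BrownianMotionModel
    root_state: float
    sigma2: float
    lambda_: float | None
    llf: float
    degenerate: bool = False
    flat_profile: bool = False

    @property
    def params(self) -> dict[str, float]:
        out = {"root_state": self.root_state, "sigma2": self.sigma2}
        if self.lambda_ is not None:
            out["lambda"] = self.lambda_
        return out

    def summary(self) -> str:
        lines = [
            "Brownian-motion trait model (ML)",
            "=" * 40,
            f"species:      {self.model.nobs}",
            f"root state:   {self.root_state: .6g}",
            f"sigma^2:      {self.sigma2: .6g}",
        ]
        if self.lambda_ is not None:
            lines.append(f"lambda:       {self.lambda_: .6g}")
        lines.append(
            f"log-lik:      {'degenerate (sigma^2 = 0)' if self.degenerate else format(self.llf, '.6g')}"
        )
        if self.flat_profile:
            lines.append("warning: flat lambda profile; boundary value returned")
        return "\n".join(lines)

    def plot_lambda_profile(self, ax=None, n_points: int = 101):
        """Plot the profile log-likelihood over lambda (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lams = np.linspace(0.0, 1.0, n_points)
        ax.plot(lams, [self.model._profile(l)[2] for l in lams], lw=1.5)
        if self.lambda_ is not None:
            ax.axvline(self.lambda_, ls="--", color="0.4")
        ax.set_xlabel("Pagel's $\\lambda$")
        ax.set_ylabel("profile log-likelihood")
        return ax

    def simulate(
        self, n_replicates: int = 1, rng: np.random.Generator | int | None = None
    ) -> np.ndarray:
        """Simulate trait vectors from the fitted parameters (rows = replicates)."""
        return simulate_bm_traits(
            self.model.tree,
            sigma2=self.sigma2,
            n_replicates=n_replicates,
            rng=rng,
            root_state=self.root_state,
            lam=1.0 if self.lambda_ is None else self.lambda_,
        )


def fit_sigma2(tree: SpeciesTree, traits: Mapping[str, float]) -> BMResults:
    """ML fit of root state and BM rate sigma^2 (lambda fixed at 1)."""
    return BrownianMotionModel(tree, traits).fit(estimate_lambda=False)


def fit_lambda_sigma2(tree: SpeciesTree, traits: Mapping[str, float]) -> BMResults:
    """Joint ML fit of root state, sigma^2 and Pagel's lambda."""
    return BrownianMotionModel(tree, traits).fit(estimate_lambda=True)


def simulate_bm_traits(
    tree: SpeciesTree,
    sigma2: float = 1.0,
    n_replicates: int = 1,
    rng: np.random.Generator | int | None = None,
    root_state: float = 0.0,
    lam: float = 1.0,
) -> np.ndarray:
    """Simulate multivariate-normal BM trait vectors on the tree.

    Returns an (n_replicates, n_species) array in tip-label order.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    V = bm_vcv(tree, sigma2)
    if lam != 1.0:
        V = lambda_transform(V, lam)
    # allow PSD-but-singular covariances (e.g. zero-length branches)
    w, U = np.linalg.eigh(V.values)
    w = np.clip(w, 0.0, None)
    A = U * np.sqrt(w)
    z = rng.standard_normal((n_replicates, len(V.labels)))
    return root_state + z @ A.T
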
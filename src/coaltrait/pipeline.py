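"""Factorial experiment orchestration: ILS conditions x locus counts x replicates.

For every (condition, locus-count) cell the pipeline calibrates the ancestral
population multiplier, simulates a trait dataset under the multispecies
coalescent, and runs the evaluation battery: across-replicate moments,
Brownian-motion rate and Pagel's lambda fits, the pair-vs-rest phylogenetic
ANOVA screen (5-species trees), and the threshold-trait incongruence tally.
One tidy CSV per analysis plus a JSON manifest is written to the output
directory.  Every cell's results depend only on the root seed and the cell's
own coordinates, so the tables are reproducible cell by cell.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anova import count_significant_groupings
from .bm import BrownianMotionModel
from .expectations import MutationModel
from .msc import (
    ILSCondition,
    Moments,
    empirical_discordance,
    simulate_trait_dataset,
    summary_moments,
)
from .threshold import compute_threshold, discretize, incongruence_frequency
from .trees import SpeciesTree, parse_newick

__all__ = ["ExperimentConfig", "run_experiment", "normalized_covariances"]

logger = logging.getLogger("coaltrait.pipeline")


@dataclass
class ExperimentConfig:
    """Flat configuration of the full factorial experiment."""

    tree: str  # Newick string or path to a Newick file
    discordance_targets: list[float] = field(default_factory=lambda: [0.0, 0.2, 0.4, 0.6, 0.8])
    locus_counts: list[int] = field(default_factory=lambda: [5, 15, 25, 50, 100])
    n_replicates: int = 1000
    theta: float = 4.0
    sigma_m2: float = 1.0
    alpha: float = 0.05
    n_null_sims: int = 1000
    calibration_sims: int = 10_000
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.discordance_targets or not self.locus_counts:
            raise ValueError("discordance_targets and locus_counts must be non-empty")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.theta <= 0 or self.sigma_m2 <= 0:
            raise ValueError("theta and sigma_m2 must be > 0")

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def species_tree(self) -> SpeciesTree:
        text = self.tree
        if not text.strip().endswith(";"):
            text = Path(text).read_text()
        return SpeciesTree(parse_newick(text))

    def fast(self) -> "ExperimentConfig":
        """Reduced-size profile: 200 replicates, 200 null sims, 4000 calibration sims."""
        d = asdict(self)
        d.update(n_replicates=min(self.n_replicates, 200),
                 n_null_sims=min(self.n_null_sims, 200),
                 calibration_sims=min(self.calibration_sims, 4000))
        return ExperimentConfig(**d)

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = asdict(self)
        d.pop("out_dir")
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _cell_seed(root_seed: int, *coords: int) -> int:
    """Deterministic per-cell seed independent of which other cells run."""
    return int(np.random.SeedSequence([root_seed, *coords]).generate_state(1)[0])


def _target_key(target: float) -> int:
    """Stable integer coordinate for a discordance target (independent of list order)."""
    return int(round(target * 10**6))


def normalized_covariances(moments: Moments, reference: str | None = None) -> pd.DataFrame:
    """Covariances divided by the variance of the reference (default: first) species."""
    ref = reference or moments.species[0]
    return pd.DataFrame(
        moments.normalized_by(ref), index=moments.species, columns=moments.species
    )


def run_experiment(config: ExperimentConfig, fast: bool = False) -> dict[str, pd.DataFrame]:
    """Run the full factorial experiment; returns (and optionally writes) tidy tables.

    Returns a dict with keys ``moments``, ``fits``, ``anova``, ``threshold``
    (tables may be empty when a stage does not apply to the tree) and
    ``manifest``.  If ``config.out_dir`` is set, CSVs and manifest.json are
    written there.
    """
    if fast:
        config = config.fast()
    tree = config.species_tree()
    n_tips = tree.tree.n_tips
    species = tree.tip_labels

    conditions: list[ILSCondition] = []
    for target in config.discordance_targets:
        cond = ILSCondition.calibrate(
            tree,
            target,
            n_sims=config.calibration_sims,
            seed=_cell_seed(config.seed, 0, _target_key(target)),
            label=f"disc{target:g}",
        )
        logger.info("condition %s: multiplier %.4g", cond.label, cond.multiplier)
        conditions.append(cond)

    moments_rows, fits_rows, anova_rows, thr_rows = [], [], [], []
    cell_meta = []
    for cond in conditions:
        ckey = _target_key(cond.target_discordance)
        for L in config.locus_counts:
            sim_seed = _cell_seed(config.seed, 1, ckey, L)
            try:
                dataset = simulate_trait_dataset(
                    tree, cond, L, MutationModel(config.theta, config.sigma_m2, L),
                    n_replicates=config.n_replicates, seed=sim_seed,
                    record_topologies=True,
                )
                obs_disc = empirical_discordance(dataset, tree)
                cell_meta.append(
                    {"condition": cond.label, "target": cond.target_discordance,
                     "multiplier": cond.multiplier, "n_loci": L, "seed": sim_seed,
                     "observed_discordance": obs_disc}
                )

                mom = summary_moments(dataset)
                norm = mom.normalized_by(species[0])
                for i, a in enumerate(species):
                    for j in range(i, len(species)):
                        b = species[j]
                        moments_rows.append(
                            {"condition": cond.label, "n_loci": L, "species_1": a,
                             "species_2": b, "moment": "variance" if i == j else "covariance",
                             "value": mom.cov[i, j], "normalized": norm[i, j]}
                        )

                if n_tips >= 3:
                    for r in range(dataset.n_replicates):
                        traits = dict(zip(species, dataset.values[r]))
                        bm_model = BrownianMotionModel(tree, traits)
                        plain = bm_model.fit(estimate_lambda=False)
                        row = {"condition": cond.label, "n_loci": L, "replicate": r,
                               "sigma2_hat": plain.sigma2, "loglik": plain.llf,
                               "root_state": plain.root_state}
                        if n_tips >= 4:
                            joint = bm_model.fit(estimate_lambda=True)
                            row.update(lambda_hat=joint.lambda_,
                                       sigma2_with_lambda=joint.sigma2,
                                       loglik_with_lambda=joint.llf)
                        fits_rows.append(row)

                if n_tips == 5:
                    rng = np.random.default_rng(_cell_seed(config.seed, 2, ckey, L))
                    mean_sig = count_significant_groupings(
                        tree, dataset, alpha=config.alpha,
                        n_null_sims=config.n_null_sims, rng=rng,
                    )
                    anova_rows.append(
                        {"condition": cond.label, "n_loci": L,
                         "mean_significant_tests": mean_sig, "alpha": config.alpha,
                         "n_null_sims": config.n_null_sims}
                    )

                if n_tips >= 4:
                    spec = compute_threshold(dataset, scope=f"{cond.label}/L{L}")
                    table = discretize(dataset, spec, tree)
                    cc = table.class_counts()
                    freq = incongruence_frequency(table)
                    thr_rows.append(
                        {"condition": cond.label, "n_loci": L, "cutoff": spec.cutoff,
                         "congruent": cc.get("congruent", 0),
                         "incongruent": cc.get("incongruent", 0),
                         "uninformative": cc.get("uninformative", 0),
                         "incongruence_frequency": freq}
                    )
            except Exception:
                logger.exception("cell (%s, L=%d) failed; continuing", cond.label, L)

    tables = {
        "moments": pd.DataFrame(moments_rows),
        "fits": pd.DataFrame(fits_rows),
        "anova": pd.DataFrame(anova_rows),
        "threshold": pd.DataFrame(thr_rows),
    }
    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "package_version": __version__,
        "species": species,
        "conditions": [asdict(c) for c in conditions],
        "cells": cell_meta,
    }
    tables["manifest"] = manifest

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("moments", "fits", "anova", "threshold"):
            tables[name].to_csv(out / f"{name}.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        logger.info("wrote results to %s", out)
    return tables
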
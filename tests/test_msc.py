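"""Multispecies-coalescent gene-tree and trait simulation against analytic oracles."""

import math

import numpy as np
import pytest

from coaltrait import (
    GeneTree,
    ILSCondition,
    MutationModel,
    SpeciesTree,
    coal_cov_nonsisters,
    coal_cov_sisters,
    coal_var,
    empirical_discordance,
    parse_newick,
    simulate_gene_tree,
    simulate_locus_contributions,
    simulate_trait_dataset,
    summary_moments,
    topology_key,
    topology_probs_3taxon,
)
from coaltrait.msc import simulate_discordance_fraction


def binom_se(p: float, n: int) -> float:
    return math.sqrt(p * (1 - p) / n)


class TestGeneTreeSimulation:
    def test_discordance_matches_analytic_multiplier_one(self, tree3, rng):
        n = 30_000
        frac = simulate_discordance_fraction(tree3, n, rng)
        expected = 2 / 3 * math.exp(-4)
        assert abs(frac - expected) <= 3 * binom_se(expected, n)

    def test_panmixia_limit_equal_topologies(self, tree3, rng):
        n = 12_000
        scaled = tree3.with_ancestral_multiplier(1e6)
        counts = {}
        for _ in range(n):
            key = simulate_gene_tree(scaled, rng=rng).topology_key()
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        for c in counts.values():
            assert abs(c / n - 1 / 3) <= 3 * binom_se(1 / 3, n)

    def test_two_tip_mrca_time(self, rng):
        """MRCA time on (A:1,B:1) is 1 + Exp(1): mean 2, within 3 MC SE."""
        tree = SpeciesTree(parse_newick("(A:1,B:1);"))
        n = 20_000
        times = np.empty(n)
        for i in range(n):
            gt = simulate_gene_tree(tree, rng=rng)
            times[i] = max(gt.node_times().values())
        assert abs(times.mean() - 2.0) <= 3 * times.std(ddof=1) / math.sqrt(n)
        assert times.min() >= 1.0

    def test_gene_tree_respects_species_divergences(self, tree3, rng):
        """Coalescences happen no more recently than the relevant species split."""
        for _ in range(300):
            gt = simulate_gene_tree(tree3, rng=rng)
            times = gt.node_times()
            by_time = sorted(
                (t for n, t in times.items() if not n.is_tip)
            )
            assert by_time[0] >= 1.0  # first coalescence after the A/B split
            assert by_time[1] >= 5.0  # root coalescence above the root split
            # parent strictly older than child along every branch
            for node in gt.tree.preorder():
                if node.parent is not None:
                    assert times[node] < times[node.parent] + 1e-12

    def test_condition_argument_scales_ancestral_populations(self, tree3, rng):
        cond = ILSCondition("high", 0.5, 50.0)
        n = 8000
        disc = sum(
            simulate_gene_tree(tree3, cond, rng).topology_key() != topology_key(tree3.tree)
            for _ in range(n)
        ) / n
        expected = 2 / 3 * math.exp(-4 / 50)
        assert abs(disc - expected) <= 3 * binom_se(expected, n)


class TestLocusContributions:
    def test_zero_theta_and_zero_effect_variance(self, rng):
        gt = GeneTree(parse_newick("((A:1,B:1):2,C:3);"))
        zero_theta = simulate_locus_contributions(gt, MutationModel(theta=1e-300), rng)
        assert all(v == 0 for v in zero_theta.values())
        no_effect = simulate_locus_contributions(
            gt, MutationModel(theta=4), rng, effect_var=0.0
        )
        assert all(v == 0 for v in no_effect.values())

    def test_star_genealogy_compound_poisson_moments(self, rng):
        """Two branches of length 1, theta=4: each species' contribution is a
        compound Poisson(2) sum of N(0,1) effects -> Var 2, Cov 0."""
        gt = GeneTree(parse_newick("(A:1,B:1);"))
        model = MutationModel(theta=4.0, sigma_m2=1.0)
        n = 20_000
        vals = np.empty((n, 2))
        for i in range(n):
            c = simulate_locus_contributions(gt, model, rng)
            vals[i] = (c["A"], c["B"])
        cov = np.cov(vals, rowvar=False)
        # Var(S^2) for compound Poisson(lambda=2, N(0,1)): kappa4 + 2 kappa2^2 = 14
        se_var = math.sqrt(14 / n)
        assert abs(cov[0, 0] - 2.0) <= 3 * se_var
        assert abs(cov[1, 1] - 2.0) <= 3 * se_var
        assert abs(cov[0, 1]) <= 3 * math.sqrt(4 / n)

    def test_mutations_shared_through_ancestral_branch(self, rng):
        """Effects on the internal branch are inherited by both descendants."""
        gt = GeneTree(parse_newick("((A:0,B:0):5,C:5);"))
        model = MutationModel(theta=4.0)
        for _ in range(50):
            c = simulate_locus_contributions(gt, model, rng)
            assert c["A"] == c["B"]  # only the shared branch can mutate


class TestTraitDataset:
    def test_determinism_bit_for_bit(self, tree3):
        cond = ILSCondition("none", 0.0, 1.0)
        kwargs = dict(n_loci=7, model=MutationModel(4, 1, 7), n_replicates=5, seed=123,
                      record_topologies=True)
        a = simulate_trait_dataset(tree3, cond, **kwargs)
        b = simulate_trait_dataset(tree3, cond, **kwargs)
        assert np.array_equal(a.values, b.values)
        assert a.topologies == b.topologies
        assert a.replicate_seeds == b.replicate_seeds

    def test_moments_match_closed_forms(self, tree3):
        """Across-replicate Var and Cov match the coalescent expectations within 3 MC SE."""
        L, n = 10, 800
        cond = ILSCondition("none", 0.0, 1.0)
        ds = simulate_trait_dataset(
            tree3, cond, L, MutationModel(4, 1, L), n_replicates=n, seed=99
        )
        mom = summary_moments(ds)
        model = MutationModel(4, 1 / L)  # per-locus prefactor theta/2 * sigma_m2/L
        exp_var = L * coal_var(4, 1, model)
        exp_ab = L * coal_cov_sisters(4, model)
        exp_ac = L * coal_cov_nonsisters(4, model)
        se_var = exp_var * math.sqrt(2 / (n - 1))
        assert abs(mom.variance("A") - exp_var) <= 3 * se_var
        se_ab = math.sqrt((exp_var**2 + exp_ab**2) / (n - 1))
        assert abs(mom.covariance("A", "B") - exp_ab) <= 3 * se_ab
        se_ac = math.sqrt((exp_var**2 + exp_ac**2) / (n - 1))
        assert abs(mom.covariance("A", "C") - exp_ac) <= 3 * se_ac
        # exchangeability of the two non-sister covariances
        assert abs(mom.covariance("A", "C") - mom.covariance("B", "C")) <= 3 * se_ac

    def test_locus_count_invariance(self, tree3):
        """With sigma_M^2/L scaling the trait moments do not depend on L."""
        n = 600
        cond = ILSCondition("none", 0.0, 1.0)
        mom = {}
        for L in (5, 100):
            ds = simulate_trait_dataset(
                tree3, cond, L, MutationModel(4, 1, L), n_replicates=n, seed=5
            )
            mom[L] = summary_moments(ds)
        exp_var = 2 * coal_var(4, 1)
        se = exp_var * math.sqrt(2 / (n - 1))
        assert abs(mom[5].variance("A") - mom[100].variance("A")) <= 3 * math.sqrt(2) * se

    def test_empirical_discordance_calibrated(self, tree3):
        cond = ILSCondition.calibrate(tree3, 0.30)
        ds = simulate_trait_dataset(
            tree3, cond, 25, MutationModel(4, 1, 25), n_replicates=1000, seed=17,
            record_topologies=True,
        )
        assert empirical_discordance(ds, tree3) == pytest.approx(0.30, abs=0.01)

    def test_discordance_independent_of_theta(self, tree3):
        cond = ILSCondition("none", 0.0, 1.0)
        kwargs = dict(n_loci=20, n_replicates=50, seed=11, record_topologies=True)
        hi = simulate_trait_dataset(tree3, cond, model=MutationModel(theta=4), **kwargs)
        lo = simulate_trait_dataset(tree3, cond, model=MutationModel(theta=0.4), **kwargs)
        assert hi.topologies == lo.topologies

    def test_moments_require_replicates_and_missing_topologies_error(self, tree3):
        cond = ILSCondition("none", 0.0, 1.0)
        ds = simulate_trait_dataset(tree3, cond, 2, n_replicates=1, seed=0)
        with pytest.raises(ValueError):
            summary_moments(ds)
        with pytest.raises(ValueError):
            empirical_discordance(ds, tree3)

    def test_dataframe_round_trip(self, tree3):
        from coaltrait.msc import TraitDataset

        cond = ILSCondition("none", 0.0, 1.0)
        ds = simulate_trait_dataset(tree3, cond, 3, n_replicates=4, seed=2)
        species, values = TraitDataset.matrix_from_table(ds.to_dataframe())
        assert species == sorted(ds.species)
        order = [ds.species.index(s) for s in species]
        assert np.allclose(values, ds.values[:, order])


class TestMsprimeCrossValidation:
    def test_topology_frequencies_match_msprime(self, tree3):
        """Independent coalescent simulator agrees on gene-tree topology frequencies.

        msprime times are in generations; with ploidy=1 and population size 1 a
        pair coalesces at rate 1 per generation, i.e. one generation equals one
        coalescent unit (2N generations) of the species tree.
        """
        msprime = pytest.importorskip("msprime")
        dem = msprime.Demography()
        for name in ("A", "B", "C", "AB", "ABC"):
            dem.add_population(name=name, initial_size=1.0)
        dem.add_population_split(time=1.0, derived=["A", "B"], ancestral="AB")
        dem.add_population_split(time=5.0, derived=["AB", "C"], ancestral="ABC")
        n = 4000
        disc = 0
        reps = msprime.sim_ancestry(
            samples={"A": 1, "B": 1, "C": 1}, demography=dem, ploidy=1,
            num_replicates=n, random_seed=42,
        )
        for ts in reps:
            t = ts.first()
            ab_mrca = t.mrca(0, 1)
            if t.mrca(0, 2) == ab_mrca or len(list(t.leaves(ab_mrca))) != 2:
                disc += 1
        expected = 2 / 3 * math.exp(-4)
        ours = simulate_discordance_fraction(tree3, n, np.random.default_rng(43))
        se = binom_se(expected, n)
        assert abs(disc / n - expected) <= 3 * se
        assert abs(ours - disc / n) <= 4 * se
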
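"""Coalescent simulator: analytic expectations, determinism, export."""

import numpy as np
import pytest

from molexpand.coalsim import (
    ConfigError,
    DemographyConfig,
    fixed_s_null,
    mismatch_counts_from_matrix,
    simulate,
    simulate_expansion_panel,
)
from molexpand.popgen_stats import diversity_from_matrix, tajimas_d
from molexpand.mismatch import expected_mismatch


def _mean_kbar(samples):
    return np.mean([diversity_from_matrix(s.genotypes).k_bar for s in samples])


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigError):
            DemographyConfig("constant", -1.0, 1.0, 0.0, 5)
        with pytest.raises(ConfigError):
            DemographyConfig("sudden_expansion", 1.0, 2.0, -0.5, 5)
        with pytest.raises(ConfigError):
            DemographyConfig("constant", 1.0, 2.0, 0.0, 5)  # theta0 != theta1
        with pytest.raises(ConfigError):
            DemographyConfig("constant", 1.0, 1.0, 0.0, 1)  # n < 2


class TestConstantSize:
    def test_zero_theta_is_monomorphic(self):
        cfg = DemographyConfig("constant", 0.0, 0.0, 0.0, 8, seed=1)
        assert simulate(cfg).S == 0

    def test_pairwise_expectation_theta_n2(self):
        # E[k̄] = θ for n = 2
        reps = 8000
        vals = [
            simulate(
                DemographyConfig("constant", 1.0, 1.0, 0.0, 2, seed=s)
            ).S
            for s in range(reps)
        ]
        mean = np.mean(vals)
        se = np.std(vals) / np.sqrt(reps)
        assert abs(mean - 1.0) < 3 * se

    @pytest.mark.parametrize("n,theta", [(5, 1.0), (20, 2.0)])
    def test_watterson_segregating_sites(self, n, theta):
        # E[S] = θ·a1, computed independently from the harmonic sum
        a1 = sum(1.0 / i for i in range(1, n))
        reps = 4000
        vals = [
            simulate(
                DemographyConfig("constant", theta, theta, 0.0, n, seed=s)
            ).S
            for s in range(reps)
        ]
        mean, se = np.mean(vals), np.std(vals) / np.sqrt(reps)
        assert abs(mean - theta * a1) < 3.5 * se

    def test_msprime_cross_check(self):
        # independent coalescent oracle under matched scaling: with haploid
        # Ne = theta, msprime's pair coalescence rate is 1/theta per
        # generation, matching our mutational-time clock, and half the
        # branch-mode diversity equals our expected pairwise difference.
        msprime = pytest.importorskip("msprime")
        theta, n, reps = 2.0, 10, 600
        ours = _mean_kbar(
            [
                simulate(
                    DemographyConfig("constant", theta, theta, 0.0, n, seed=s)
                )
                for s in range(reps)
            ]
        )
        acc = 0.0
        for s in range(reps):
            ts = msprime.sim_ancestry(
                samples=n, ploidy=1, population_size=theta, random_seed=s + 1
            )
            acc += ts.diversity(mode="branch", span_normalise=False)
        theirs = 0.5 * acc / reps
        assert ours == pytest.approx(theirs, rel=0.08)


class TestSuddenExpansion:
    def test_collapses_to_constant_when_tau_zero(self):
        reps = 3000
        exp_panel = simulate_expansion_panel(2.0, 2.0, 0.0, 6, reps, seed=5)
        const = [
            simulate(DemographyConfig("constant", 2.0, 2.0, 0.0, 6, seed=s))
            for s in range(reps)
        ]
        assert _mean_kbar(exp_panel) == pytest.approx(
            _mean_kbar(const), rel=0.08
        )

    def test_poisson_limit_mean_tau(self):
        # theta0=0, theta1 huge: pairwise differences ~ Poisson(tau)
        panel = simulate_expansion_panel(0.0, 1e4, 3.0, 50, 400, seed=3)
        assert _mean_kbar(panel) == pytest.approx(3.0, abs=0.15)

    def test_pooled_mismatch_matches_closed_form(self):
        # total variation < 0.03 against the transient formula
        tau, th0, th1, n = 4.0, 1.0, 100.0, 50
        panel = simulate_expansion_panel(th0, th1, tau, n, 2000, seed=17)
        pool = np.zeros(500)
        for s in panel:
            c = mismatch_counts_from_matrix(s.genotypes)
            pool[: len(c)] += c / c.sum()
        pool /= len(panel)
        d_max = len(pool) - 1
        expv = expected_mismatch(tau, th0, th1, d_max)
        tv = 0.5 * (np.abs(pool - expv).sum() + max(0.0, 1 - expv.sum()))
        assert tv < 0.03

    def test_determinism_and_substreams(self):
        p1 = simulate_expansion_panel(1.0, 100.0, 2.0, 8, 3, seed=9)
        p2 = simulate_expansion_panel(1.0, 100.0, 2.0, 8, 3, seed=9)
        for a, b in zip(p1, p2):
            assert np.array_equal(a.genotypes, b.genotypes)
        # distinct replicates are not identical
        assert not np.array_equal(p1[0].genotypes, p1[1].genotypes)


class TestFixedSNull:
    def test_s_zero_monomorphic(self):
        for s in fixed_s_null(6, 0, 5, seed=2):
            assert s.S == 0

    def test_n2_every_replicate_has_difference_s(self):
        for s in fixed_s_null(2, 5, 20, seed=4):
            counts = mismatch_counts_from_matrix(s.genotypes)
            assert counts[5] == 1 and counts.sum() == 1

    def test_mean_tajimas_d_near_zero(self):
        # empirical null mean of D under conditional-on-S simulation
        vals = []
        for s in fixed_s_null(10, 10, 3000, seed=6):
            d = diversity_from_matrix(s.genotypes)
            vals.append(tajimas_d(10, d.S, d.k_bar))
        assert -0.3 < np.mean(vals) < 0.3


class TestExport:
    def test_alignment_export_roundtrip_distances(self):
        cfg = DemographyConfig(
            "sudden_expansion", 0.5, 200.0, 2.0, 12, k=1140, seed=21
        )
        sample = simulate(cfg)
        aln = sample.to_alignment()
        assert aln.n == 12 and aln.k == 1140
        # infinite-sites export preserves every pairwise distance
        from molexpand.mismatch import observed_mismatch

        direct = mismatch_counts_from_matrix(sample.genotypes)
        via_seq = observed_mismatch(aln).counts
        assert np.array_equal(
            np.trim_zeros(direct, "b"), np.trim_zeros(via_seq, "b")
        )

    def test_exchangeability_of_downstream_statistics(self):
        cfg = DemographyConfig(
            "sudden_expansion", 0.5, 200.0, 2.0, 10, seed=8
        )
        g = simulate(cfg).genotypes
        perm = np.random.default_rng(0).permutation(g.shape[0])
        a = diversity_from_matrix(g)
        b = diversity_from_matrix(g[perm])
        assert (a.S, a.k_bar) == (b.S, b.k_bar)
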
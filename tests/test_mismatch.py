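"""Mismatch distributions, the sudden-expansion model and its fit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from molexpand.seq_io import Alignment, HaplotypeTable, collapse_haplotypes
from molexpand.mismatch import (
    MismatchDistribution,
    equilibrium_mismatch,
    expected_mismatch,
    fit_sudden_expansion,
    observed_mismatch,
    parametric_bootstrap,
    raggedness,
)


class TestObservedMismatch:
    def test_direct_enumeration_three_sequences(self):
        # pairwise differences by hand: ab=1, bc=1, ac=2
        aln = Alignment(
            records=[("a", "AAAA"), ("b", "AAAT"), ("c", "AATT")]
        )
        obs = observed_mismatch(aln)
        assert obs.counts[1] == 2 and obs.counts[2] == 1
        assert obs.n_pairs == 3

    def test_monomorphic_all_pairs_at_zero(self):
        aln = Alignment(records=[(f"s{i}", "ACGT") for i in range(5)])
        obs = observed_mismatch(aln)
        assert obs.counts[0] == 10 and obs.n_pairs == 10

    def test_haplotype_frequency_weighting(self):
        # {(h1, 2), (h2, 3)} with d(h1,h2)=4: brute-force pair expansion
        # gives counts[0] = C(2,2)+C(3,2) = 4 and counts[4] = 2*3 = 6
        table = HaplotypeTable(
            haplotypes=[
                ("AAAAAA", 2, ["a", "b"]),
                ("TTTTAA", 3, ["c", "d", "e"]),
            ],
            n=5,
        )
        obs = observed_mismatch(table)
        assert obs.counts[0] == 4 and obs.counts[4] == 6
        assert obs.n_pairs == 10

    def test_table_agrees_with_raw_alignment(self, toy_alignment):
        direct = observed_mismatch(toy_alignment)
        via_table = observed_mismatch(collapse_haplotypes(toy_alignment))
        assert np.array_equal(direct.counts, via_table.counts)


class TestExpectedMismatch:
    def test_equilibrium_closed_form_theta_one(self):
        f = equilibrium_mismatch(1.0, 2)
        assert np.allclose(f, [0.5, 0.25, 0.125])

    def test_equilibrium_theta_zero_point_mass(self):
        f = equilibrium_mismatch(0.0, 3)
        assert np.allclose(f, [1, 0, 0, 0])

    def test_equilibrium_truncation_mass_geometric(self):
        theta, d_max = 2.5, 30
        f = equilibrium_mismatch(theta, d_max)
        assert 1 - f.sum() == pytest.approx(
            (theta / (theta + 1)) ** (d_max + 1), rel=1e-12
        )

    def test_transient_reduces_to_equilibrium_at_tau_zero(self):
        assert np.allclose(
            expected_mismatch(0.0, 0.7, 0.7, 25),
            equilibrium_mismatch(0.7, 25),
        )

    def test_poisson_limit(self):
        from scipy.stats import poisson

        f = expected_mismatch(2.5, 0.0, 1e6, 12)
        assert np.allclose(f, poisson.pmf(np.arange(13), 2.5), atol=1e-5)

    def test_large_tau_limit_is_new_equilibrium(self):
        f = expected_mismatch(500.0, 1.0, 5.0, 40)
        assert np.allclose(f, equilibrium_mismatch(5.0, 40), atol=1e-10)

    @given(
        tau=st.floats(min_value=0.0, max_value=15.0),
        th0=st.floats(min_value=0.0, max_value=5.0),
        th1=st.floats(min_value=0.1, max_value=500.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_normalizes_and_is_nonnegative(self, tau, th0, th1):
        d_max = 220 + int(tau + th0)
        f = expected_mismatch(tau, th0, th1, d_max)
        assert (f > -1e-12).all()
        assert f.sum() <= 1 + 1e-9

    def test_mean_in_infinite_growth_limit_is_tau_plus_theta0(self):
        tau, th0 = 3.0, 1.2
        d = np.arange(400)
        f = expected_mismatch(tau, th0, 1e7, 399)
        assert (d * f).sum() == pytest.approx(tau + th0, abs=1e-3)


class TestRaggedness:
    def test_point_mass_gives_one(self):
        assert raggedness(np.array([1.0])) == pytest.approx(1.0)

    def test_two_equal_bins(self):
        assert raggedness(np.array([0.5, 0.5])) == pytest.approx(0.25)

    def test_uniform_support_small_and_smooth_below_spiky(self):
        smooth = raggedness(np.full(10, 0.1))
        assert smooth == pytest.approx(0.01)
        spiky = raggedness(np.array([0.3, 0.0, 0.3, 0.0, 0.3, 0.1]))
        assert smooth < spiky


class TestFit:
    def test_self_consistency_on_noiseless_input(self):
        exp = expected_mismatch(3.0, 1.0, 1000.0, 40)
        counts = np.round(exp * 1e7).astype(np.int64)
        fit = fit_sudden_expansion(MismatchDistribution(counts=counts))
        assert fit.tau == pytest.approx(3.0, abs=0.05)
        assert fit.ssd < 1e-8

    def test_monomorphic_fit_is_degenerate(self):
        obs = MismatchDistribution(counts=np.array([10]))
        fit = fit_sudden_expansion(obs)
        assert fit.tau == 0.0 and fit.theta0 == 0.0
        assert fit.degenerate

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(1)
        counts = rng.multinomial(500, expected_mismatch(2.0, 0.5, 300.0, 20))
        a = fit_sudden_expansion(MismatchDistribution(counts=counts))
        b = fit_sudden_expansion(MismatchDistribution(counts=counts))
        assert (a.tau, a.theta0, a.theta1, a.ssd) == (
            b.tau, b.theta0, b.theta1, b.ssd,
        )


class TestBootstrap:
    def test_same_seed_identical_results(self):
        from molexpand import coalsim

        sim = coalsim.simulate(
            coalsim.DemographyConfig(
                "sudden_expansion", 1.0, 1000.0, 3.0, 30, seed=4
            )
        )
        counts = coalsim.mismatch_counts_from_matrix(sim.genotypes)
        fit = fit_sudden_expansion(MismatchDistribution(counts=counts))
        a = parametric_bootstrap(fit, n=30, reps=120, seed=7)
        b = parametric_bootstrap(fit, n=30, reps=120, seed=7)
        assert (a.p_ssd, a.p_raggedness, a.tau_ci) == (
            b.p_ssd, b.p_raggedness, b.tau_ci,
        )
        assert 0 < a.p_ssd <= 1 and 0 < a.p_raggedness <= 1

    def test_model_not_rejected_on_model_data(self):
        # one well-behaved dataset drawn from the model itself should give
        # an unremarkable SSD p-value (full type-I study in acceptance)
        from molexpand import coalsim

        sim = coalsim.simulate(
            coalsim.DemographyConfig(
                "sudden_expansion", 1.0, 1000.0, 3.0, 50, seed=123
            )
        )
        counts = coalsim.mismatch_counts_from_matrix(sim.genotypes)
        fit = fit_sudden_expansion(MismatchDistribution(counts=counts))
        done = parametric_bootstrap(fit, n=50, reps=150, seed=9)
        assert done.p_ssd > 0.05
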
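"""Histogram fitting, separation metrics, agreement, and regressions."""

import numpy as np
import pytest

from datspect.cohort_stats import (
    FitError,
    GaussianPairFit,
    classify,
    cohens_kappa,
    cross_tab,
    cutoff,
    effect_size,
    fit_sbr_values,
    fit_two_gaussians,
    histogram_sbr,
    regress,
    subsample_stability,
)

TABLE_MIX = dict(m1=0.58, sd1=0.15, m2=1.57, sd2=0.32, p1=0.45)


def draw_mixture(n, seed, m1, sd1, m2, sd2, p1):
    rng = np.random.default_rng(seed)
    reduced = rng.random(n) < p1
    vals = np.where(
        reduced, rng.normal(m1, sd1, n), rng.normal(m2, sd2, n)
    )
    return vals[vals > -0.5]


class TestHistogram:
    def test_direct_binning(self):
        centers, counts = histogram_sbr([0.05, 0.05, 0.15])
        assert np.allclose(centers, [0.05, 0.15])
        assert counts.tolist() == [2, 1]

    def test_counts_conserved_and_negative_bins(self, rng):
        vals = rng.normal(0.2, 0.5, 500)
        centers, counts = histogram_sbr(vals)
        assert counts.sum() == vals.size
        assert centers.min() < 0  # negative SBR lands in negative-k bins

    def test_mode_near_distribution_mean(self):
        vals = np.random.default_rng(8).normal(1.0, 0.3, 10_000)
        centers, counts = histogram_sbr(vals)
        assert abs(centers[np.argmax(counts)] - 1.0) <= 0.1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            histogram_sbr([])


class TestFitTwoGaussians:
    def test_exact_model_inversion(self):
        """A histogram synthesized exactly from the two-Gaussian model is
        inverted to the generating parameters."""
        centers = np.arange(0.05, 3.06, 0.1)
        truth = (50.0, 0.6, 0.18, 40.0, 1.7, 0.36)
        counts = GaussianPairFit(*truth).model(centers)
        fit = fit_two_gaussians(centers, counts)
        assert fit.sse < 1e-6 * np.sum(counts**2)
        for got, want in zip(
            (fit.a1, fit.m1, fit.sd1, fit.a2, fit.m2, fit.sd2), truth
        ):
            assert got == pytest.approx(want, abs=1e-3)

    def test_mixture_draw_recovery(self):
        """1702 draws from the fitted cohort mixture: recovered means within
        0.05 and SDs within 0.04 of the generating values."""
        vals = draw_mixture(1702, seed=123, **TABLE_MIX)
        fit = fit_sbr_values(vals)
        assert fit.m1 == pytest.approx(TABLE_MIX["m1"], abs=0.05)
        assert fit.m2 == pytest.approx(TABLE_MIX["m2"], abs=0.05)
        assert fit.sd1 == pytest.approx(TABLE_MIX["sd1"], abs=0.04)
        assert fit.sd2 == pytest.approx(TABLE_MIX["sd2"], abs=0.04)

    def test_single_component_degenerates_gracefully(self):
        vals = np.random.default_rng(3).normal(1.5, 0.3, 2000)
        fit = fit_sbr_values(vals)
        # either flagged, a negligible second amplitude, or both components
        # collapsed onto the single mode
        collapsed = abs(fit.m1 - fit.m2) < 0.3
        assert (not fit.converged) or min(abs(fit.a1), abs(fit.a2)) < 0.05 * max(
            abs(fit.a1), abs(fit.a2)
        ) or collapsed

    def test_too_few_bins_rejected(self):
        with pytest.raises(FitError):
            fit_two_gaussians(np.array([0.05, 0.15, 0.25]), np.array([1, 2, 1]))

    def test_components_relabeled_by_mean(self):
        centers = np.arange(0.05, 3.06, 0.1)
        counts = GaussianPairFit(40.0, 1.7, 0.36, 50.0, 0.6, 0.18).model(centers)
        fit = fit_two_gaussians(centers, counts)
        assert fit.m1 <= fit.m2
        assert fit.m1 == pytest.approx(0.6, abs=1e-3)


class TestEffectSizeAndCutoff:
    @pytest.mark.parametrize(
        "m1, sd1, m2, sd2, expected",
        [
            (0.63, 0.18, 1.72, 0.36, 3.83),  # hottest-voxels min, single template
            (0.58, 0.15, 1.57, 0.32, 3.96),  # hottest-voxels min, multi-template
            (0.0, 1.0, 1.0, 1.0, 1.0),
        ],
    )
    def test_effect_size_worked_examples(self, m1, sd1, m2, sd2, expected):
        assert round(effect_size(m1, sd1, m2, sd2), 2) == expected

    def test_cutoff_symmetric_sds_is_midpoint(self):
        assert cutoff(1.0, 0.2, 2.0, 0.2) == pytest.approx(1.5)

    def test_cutoff_equal_means(self):
        assert cutoff(1.2, 0.1, 1.2, 0.4) == pytest.approx(1.2)

    def test_cutoff_direct_evaluation(self):
        # from the printed fit parameters; the paper's own unrounded fit
        # prints 0.995
        assert cutoff(0.63, 0.18, 1.72, 0.36) == pytest.approx(0.9933, abs=5e-4)

    def test_shift_invariance_of_d_and_equivariance_of_c(self):
        d0 = effect_size(0.6, 0.2, 1.6, 0.3)
        c0 = cutoff(0.6, 0.2, 1.6, 0.3)
        assert effect_size(1.1, 0.2, 2.1, 0.3) == pytest.approx(d0, rel=1e-12)
        assert cutoff(1.1, 0.2, 2.1, 0.3) == pytest.approx(c0 + 0.5, rel=1e-12)


class TestClassify:
    def test_threshold_and_tie_rule(self):
        labels = classify(np.array([0.9, 1.1, 1.0]), 1.0)
        assert labels.tolist() == ["reduced", "normal", "normal"]


class TestSubsampleStability:
    def test_full_fraction_degenerate_sd_zero(self):
        vals = draw_mixture(300, seed=1, **TABLE_MIX)
        mean_d, sd_d, cov = subsample_stability(vals, n_rep=10, frac=1.0, seed=0)
        assert sd_d == 0.0
        assert cov == 0.0

    def test_seeded_reproducibility(self):
        vals = draw_mixture(400, seed=2, **TABLE_MIX)
        out1 = subsample_stability(vals, n_rep=20, frac=0.9, seed=7)
        out2 = subsample_stability(vals, n_rep=20, frac=0.9, seed=7)
        assert out1 == out2

    def test_small_subsample_rejected(self):
        with pytest.raises(ValueError):
            subsample_stability(np.ones(40), n_rep=5, frac=0.9, seed=0)


class TestCrossTabAndKappa:
    def test_identical_labels_diagonal(self):
        a = np.array(["normal", "reduced", "normal"])
        tab = cross_tab(a, a)
        assert tab["counts"][0, 1] == 0 and tab["counts"][1, 0] == 0
        assert tab["concordance"] == 1.0

    def test_printed_cross_table_percentages(self):
        counts = np.array([[930, 8], [29, 735]])
        pct = counts / counts.sum() * 100
        assert np.round(pct, 1).tolist() == [[54.6, 0.5], [1.7, 43.2]]
        assert round(np.trace(counts) / counts.sum() * 100, 1) == 97.8

    def test_kappa_printed_value_and_se(self):
        kappa, se = cohens_kappa(np.array([[930, 8], [29, 735]]))
        assert round(kappa, 3) == 0.956
        assert se == pytest.approx(0.007, abs=5e-4)

    def test_kappa_perfect_and_independent(self):
        k, _ = cohens_kappa(np.array([[50, 0], [0, 50]]))
        assert k == pytest.approx(1.0)
        k, _ = cohens_kappa(np.array([[36, 24], [24, 16]]))  # marginal product
        assert k == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_tab(np.array(["normal"]), np.array(["normal", "reduced"]))


class TestRegress:
    def test_proportional_no_constant(self):
        x = np.linspace(1, 10, 30)
        r = regress(2 * x, x, with_constant=False)
        assert r.slope == pytest.approx(2.0)
        assert r.beta == pytest.approx(1.0, abs=1e-9)
        assert r.p_value < 1e-20

    def test_affine_with_constant(self):
        x = np.linspace(0, 5, 25)
        r = regress(x + 1, x, with_constant=True)
        assert r.slope == pytest.approx(1.0)
        assert r.intercept == pytest.approx(1.0)

    def test_null_simulation_beta_small(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10_000)
        y = rng.normal(size=10_000)
        r = regress(y, x, with_constant=True)
        assert abs(r.beta) < 0.05

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            regress(np.arange(5.0), np.ones(5))
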
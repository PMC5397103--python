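"""Histograms, FWHH, the isotropic kappa^2 density, and width comparisons."""

import math

import numpy as np
import pytest
from scipy import integrate

from fretkappa import (
    FretParameters,
    compare_true_vs_apparent,
    distance_series_summary,
    fwhh,
    instantaneous_efficiency,
    isotropic_kappa2_pdf,
    make_histogram,
    reconstruct_apparent_distribution,
    simulate_isotropic_kappa2,
    summarize,
)
from fretkappa.synthetic import LinkerModelParams, simulate_relaxing_distance_series


class TestMakeHistogram:
    def test_constant_samples_single_bin(self):
        h = make_histogram(np.full(1000, 5.0), 1.0)
        assert h.counts.sum() == 1000
        occupied = np.flatnonzero(h.counts)
        assert occupied.size == 1
        i = occupied[0]
        assert h.bin_edges[i] <= 5.0 <= h.bin_edges[i + 1]
        assert h.density[i] == pytest.approx(1.0)

    def test_uniform_samples_flat_density(self):
        rng = np.random.default_rng(5)
        h = make_histogram(rng.uniform(0, 1, 200_000), 0.1)
        np.testing.assert_allclose(h.density[h.counts > 0], 1.0, atol=0.05)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(6)
        for scale in (0.1, 3.0, 40.0):
            h = make_histogram(rng.normal(0, scale, 5000), scale / 7.0)
            assert float(np.sum(h.density * h.widths)) == pytest.approx(1.0, abs=1e-9)

    def test_edges_aligned_to_bin_width(self):
        h = make_histogram([3.2, 7.9], 0.5)
        np.testing.assert_allclose(h.bin_edges / 0.5, np.round(h.bin_edges / 0.5), atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            make_histogram([], 1.0)


class TestFwhh:
    @pytest.mark.parametrize("sigma", [1.0, 2.0])
    def test_gaussian_width_matches_closed_form(self, sigma):
        rng = np.random.default_rng(8)
        h = make_histogram(rng.normal(0, sigma, 1_000_000), sigma / 20.0)
        expected = 2.0 * math.sqrt(2.0 * math.log(2.0)) * sigma
        assert fwhh(h) == pytest.approx(expected, rel=0.02)

    def test_single_occupied_bin_convention(self):
        h = make_histogram(np.full(100, 5.2), 1.0)
        assert fwhh(h) == pytest.approx(1.0)

    def test_flat_histogram_rejected(self):
        from fretkappa import Histogram

        h = Histogram(  # two equally occupied bins: no defined peak
            bin_edges=np.array([0.0, 1.0, 2.0]),
            counts=np.array([5, 5]),
            density=np.array([0.5, 0.5]),
        )
        with pytest.raises(ValueError, match="peak"):
            fwhh(h)


class TestIsotropicKappa2Pdf:
    def test_normalization_by_quadrature(self):
        # substitute k = u^2 to tame the inverse-square-root singularity at 0
        val, _ = integrate.quad(lambda u: 2 * u * isotropic_kappa2_pdf(u * u), 1e-12, 2.0, points=[1.0])
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_mean_is_two_thirds(self):
        val, _ = integrate.quad(
            lambda u: 2 * u**3 * isotropic_kappa2_pdf(u * u), 1e-12, 2.0, points=[1.0]
        )
        assert val == pytest.approx(2.0 / 3.0, abs=1e-6)

    def test_support_and_monotonicity(self):
        low = np.linspace(0.01, 1.0, 200)
        high = np.linspace(1.0 + 1e-9, 4.0, 200)
        assert np.all(np.diff(isotropic_kappa2_pdf(low)) < 0)
        assert np.all(np.diff(isotropic_kappa2_pdf(high)) < 0)
        assert isotropic_kappa2_pdf(4.5) == 0.0
        with pytest.raises(ValueError):
            isotropic_kappa2_pdf(0.0)

    def test_monte_carlo_histogram_matches_closed_form(self):
        """Sup distance between a large MC histogram and the bin-averaged density."""
        k2 = simulate_isotropic_kappa2(1_000_000, seed=42)
        h = make_histogram(k2, 0.05)
        centers_ok = slice(1, None)  # first bin holds the integrable singularity
        bin_avg = np.array(
            [
                integrate.quad(isotropic_kappa2_pdf, max(a, 1e-12), b)[0] / (b - a)
                for a, b in zip(h.bin_edges[:-1], h.bin_edges[1:])
            ]
        )
        sup = np.max(np.abs(h.density[centers_ok] - bin_avg[centers_ok]))
        assert sup < 0.01


class TestApparentReconstruction:
    def test_delta_efficiency_maps_to_forster_radius_bin(self):
        rec = reconstruct_apparent_distribution(np.full(500, 0.5), 48.0, 1.0)
        occupied = np.flatnonzero(rec.histogram.counts)
        assert occupied.size == 1
        i = occupied[0]
        assert rec.histogram.bin_edges[i] <= 48.0 <= rec.histogram.bin_edges[i + 1]
        assert rec.n_excluded == 0

    def test_zero_efficiencies_excluded_with_count(self):
        eff = np.array([0.0, 0.5, 0.6, 1.0, 0.4])
        rec = reconstruct_apparent_distribution(eff, 48.0, 1.0)
        assert rec.n_excluded == 2
        assert rec.histogram.counts.sum() == 3

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_apparent_distribution(np.zeros(5), 48.0, 1.0)

    def test_orientation_noise_alone_broadens_apparent_distribution(self):
        """A zero-width true distance still yields a finite apparent width."""
        params = FretParameters(r0_ref=48.0, kappa2_ref=2.0 / 3.0)
        k2 = simulate_isotropic_kappa2(100_000, seed=3)
        eff = instantaneous_efficiency(np.full(k2.size, 44.0), k2, params)
        rec = reconstruct_apparent_distribution(eff, 48.0, 1.0)
        assert rec.summary.fwhh > 1.0  # wider than a single 1 A bin


class TestCompareTrueVsApparent:
    def test_identical_samples_have_unit_ratio(self):
        rng = np.random.default_rng(12)
        x = rng.normal(44.0, 3.0, 50_000)
        h = make_histogram(x, 1.0)
        c = compare_true_vs_apparent(x, h, 1.0)
        assert c.width_ratio == pytest.approx(1.0, rel=1e-9)

    def test_gaussian_true_with_isotropic_kappa2_inflates_width(self):
        params = FretParameters(r0_ref=48.0, kappa2_ref=2.0 / 3.0)
        rng = np.random.default_rng(21)
        n = 100_000
        r_true = np.abs(rng.normal(44.0, 2.0, n))
        k2 = simulate_isotropic_kappa2(n, seed=22)
        eff = instantaneous_efficiency(r_true, k2, params)
        rec = reconstruct_apparent_distribution(eff, 48.0, 1.0)
        c = compare_true_vs_apparent(r_true, rec.histogram, 1.0, n_excluded_apparent=rec.n_excluded)
        assert c.width_ratio > 1.0
        assert c.apparent_summary.fwhh > c.true_summary.fwhh

    def test_degenerate_true_distribution_flagged_infinite(self):
        h = make_histogram(np.linspace(30, 60, 1000), 1.0)
        c = compare_true_vs_apparent(np.full(100, 44.0), h, 1.0)
        assert math.isinf(c.width_ratio)


class TestDistanceSeriesSummary:
    def test_constant_series(self):
        s = distance_series_summary(np.full(50, 44.0), window=5)
        np.testing.assert_allclose(s.table["running_mean"], 44.0)
        assert s.overall_mean == pytest.approx(44.0)
        assert s.tail_mean == pytest.approx(44.0)

    def test_window_one_is_identity(self):
        x = np.arange(101, dtype=float)
        s = distance_series_summary(x, window=1)
        np.testing.assert_allclose(s.table["running_mean"], x)

    def test_relaxing_series_tail_mean_recovers_plateau(self):
        params = LinkerModelParams(
            n_frames=1000, mean_A=44.0, sd_A=1.0, start_A=90.0,
            relaxation_tau_frames=100, seed=33,
        )
        series = simulate_relaxing_distance_series(params)
        s = distance_series_summary(series, window=50)
        se = 1.0 / math.sqrt(1000 / 3)
        # exp(-t/tau) contributes < 0.2 A on the final third; allow it plus noise
        assert abs(s.tail_mean - 44.0) < 3 * se + 0.2

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            distance_series_summary(np.ones(10), window=11)


def test_summarize_reports_moments_and_fwhh():
    rng = np.random.default_rng(14)
    x = rng.normal(10.0, 2.0, 200_000)
    s = summarize(x, 0.1)
    assert s.mean == pytest.approx(10.0, abs=0.05)
    assert s.standard_deviation == pytest.approx(2.0, abs=0.05)
    assert s.fwhh == pytest.approx(2.0 * math.sqrt(2.0 * math.log(2.0)) * 2.0, rel=0.03)
    assert s.n_samples == 200_000
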
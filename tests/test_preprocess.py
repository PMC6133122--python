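"""Referencing, baseline removal, QC gating, binning and transforms."""

import numpy as np
import pytest

from nephromet.preprocess import (BinFeatureTable, BinningConfig, BinStats,
                                  QCThresholds, ReferencingError,
                                  bin_spectrum, correct_baseline,
                                  normalize_total_integral, qc_filter,
                                  reference_to_tsp, transform_bins)
from nephromet.quantify import pseudo_voigt
from nephromet.synthetic import generate_spectrum


class TestReferencing:
    def test_shifted_tsp_restored_to_zero(self, clean_config):
        sp = generate_spectrum({}, clean_config).shifted(0.03)
        ref = reference_to_tsp(sp)
        i = np.argmax(ref.intensities)
        assert abs(ref.ppm[i]) <= 0.5 * ref.ppm_step

    def test_identity_when_already_referenced(self, clean_config):
        sp = generate_spectrum({}, clean_config)
        ref = reference_to_tsp(sp)
        assert abs(ref.ppm_start - sp.ppm_start) <= 0.5 * sp.ppm_step

    def test_idempotent(self, clean_config):
        sp = generate_spectrum({}, clean_config).shifted(0.05)
        once = reference_to_tsp(sp)
        twice = reference_to_tsp(once)
        assert abs(twice.ppm_start - once.ppm_start) <= 0.5 * sp.ppm_step

    def test_missing_tsp_raises(self, default_config):
        cfg = default_config
        sp = generate_spectrum({"lactate": 1.0},
                               cfg.__class__(**{**cfg.__dict__,
                                                "tsp_area": 0.0}))
        with pytest.raises(ReferencingError):
            reference_to_tsp(sp)


class TestBaseline:
    def test_zero_baseline_nearly_unchanged(self, clean_config):
        sp = generate_spectrum({"lactate": 1.0, "creatinine": 8.0},
                               clean_config)
        corr = correct_baseline(sp)
        peak_height = sp.intensities.max()
        assert np.max(np.abs(corr.intensities - sp.intensities)) \
            < 2e-3 * peak_height

    def test_linear_baseline_removed(self, clean_config):
        cfg = clean_config.__class__(**{**clean_config.__dict__,
                                        "baseline_params": (2.0, 0.5)})
        corr = correct_baseline(generate_spectrum({"lactate": 1.0}, cfg))
        for region in ((6.0, 7.0), (8.5, 9.4)):
            _, y = corr.slice(*region)
            original = 2.0 + 0.5 * np.mean(region)
            assert abs(np.mean(y)) < 0.01 * original

    def test_constant_offset_fully_absorbed(self, clean_config):
        """Additivity: correcting y + c gives the same result as correcting y
        (the estimated baseline shifts by exactly c)."""
        sp = generate_spectrum({"creatinine": 8.0}, clean_config)
        offset = 5.0
        raised = sp.shifted(0.0)
        raised.intensities = sp.intensities + offset
        corr0 = correct_baseline(sp)
        corr1 = correct_baseline(raised)
        peak = sp.intensities.max()
        assert np.max(np.abs(corr1.intensities - corr0.intensities)) \
            < 1e-6 * peak


class TestQC:
    def test_clean_spectrum_passes(self, default_config):
        sp = generate_spectrum({"lactate": 1.0, "creatinine": 8.0},
                               default_config)
        sp = correct_baseline(reference_to_tsp(sp))
        report = qc_filter(sp)
        assert report.passed and report.reasons == []

    def test_injected_slope_fails_slope_check(self, default_config):
        sp = generate_spectrum({"lactate": 1.0}, default_config)
        sp = correct_baseline(reference_to_tsp(sp))
        thr = QCThresholds()
        sp.intensities = sp.intensities + 10 * thr.max_baseline_slope * sp.ppm
        report = qc_filter(sp, thr)
        assert not report.passed
        assert any(r.startswith("baseline_slope") for r in report.reasons)

    def test_wide_reference_fails_width_check(self, clean_config, templates):
        wide = 5 * templates["tsp"].fwhm
        sp_factory_cfg = clean_config

        def widened(ppm):
            return pseudo_voigt(ppm, 0.0, 2.0, wide, 0.5)

        sp = generate_spectrum({}, sp_factory_cfg)
        sp.intensities = widened(sp.ppm)
        report = qc_filter(sp)
        assert not report.passed and "reference_width" in report.reasons

    def test_fail_never_flips_back_with_larger_artifact(self, default_config):
        """QC monotonicity: growing an injected slope cannot restore a pass."""
        base = generate_spectrum({"lactate": 1.0}, default_config)
        base = correct_baseline(reference_to_tsp(base))
        thr = QCThresholds()
        failed_before = False
        for mult in (0.1, 0.5, 2.0, 5.0, 20.0):
            sp = base.shifted(0.0)
            sp.intensities = base.intensities \
                + mult * thr.max_baseline_slope * sp.ppm
            passed = qc_filter(sp, thr).passed
            if failed_before:
                assert not passed
            failed_before = failed_before or not passed
        assert failed_before


class TestBinning:
    def test_default_layout_yields_377_bins(self):
        cfg = BinningConfig()
        edges = cfg.edges()
        assert edges.shape == (377, 2)
        widths = edges[:, 1] - edges[:, 0]
        np.testing.assert_allclose(widths, cfg.bin_width, atol=1e-12)
        # no bin intrudes into the excluded water region
        for lo, hi in cfg.excluded_regions:
            assert not np.any((edges[:, 0] < hi) & (edges[:, 1] > lo))

    def test_constant_spectrum_gives_width_times_height(self, spectrum_factory):
        h = 3.7
        sp = spectrum_factory(lambda ppm: np.full_like(ppm, h))
        values = bin_spectrum(sp)
        np.testing.assert_allclose(values, h * BinningConfig().bin_width,
                                   atol=1e-9)

    def test_isolated_peak_lands_in_one_bin(self, spectrum_factory):
        cfg = BinningConfig()
        edges = cfg.edges()
        lo, hi = edges[40]
        center = 0.5 * (lo + hi)
        area, fwhm = 2.0, 0.002
        sp = spectrum_factory(
            lambda ppm: pseudo_voigt(ppm, center, area, fwhm, 0.0))
        values = bin_spectrum(sp, cfg)
        # quadrature oracle: nearly all Gaussian area inside the 0.022 bin
        assert values[40] == pytest.approx(area, rel=1e-3)
        others = np.delete(values, 40)
        assert np.max(np.abs(others)) < 1e-3 * area

    def test_range_outside_grid_rejected(self, spectrum_factory):
        sp = spectrum_factory(lambda ppm: np.zeros_like(ppm), ppm_stop=5.0)
        with pytest.raises(ValueError):
            bin_spectrum(sp, BinningConfig())


def _table(values):
    values = np.asarray(values, dtype=float)
    n_bins = values.shape[1]
    edges = np.column_stack([np.arange(n_bins) * 0.02,
                             (np.arange(n_bins) + 1) * 0.02])
    return BinFeatureTable(bin_edges=edges, values=values, stage="raw",
                           excluded_regions=())


class TestNormalization:
    def test_worked_example(self):
        out = normalize_total_integral(_table([[2.0, 3.0, 5.0]]))
        np.testing.assert_allclose(out.values, [[0.2, 0.3, 0.5]])
        assert out.stage == "normalized"

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(4)
        out = normalize_total_integral(_table(rng.random((30, 12)) + 0.1))
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        base = rng.random((5, 8)) + 0.1
        a = normalize_total_integral(_table(base))
        b = normalize_total_integral(_table(10.0 * base))
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)

    def test_zero_row_flagged_invalid(self):
        out = normalize_total_integral(_table([[1.0, 1.0], [0.0, 0.0]]))
        assert out.valid.tolist() == [True, False]
        assert np.isnan(out.values[1]).all()


class TestTransform:
    def test_signed_cube_root(self):
        table = _table([[0.008, -0.001], [0.027, 0.001]])
        out, _ = transform_bins(table)
        rooted = np.cbrt(table.values)
        assert rooted[0, 0] == pytest.approx(0.2)
        assert rooted[0, 1] == pytest.approx(-0.1)
        assert out.stage == "autoscaled"

    def test_training_columns_standardized(self):
        rng = np.random.default_rng(6)
        out, stats = transform_bins(_table(rng.random((50, 7))))
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-6)
        np.testing.assert_allclose(out.values.std(axis=0), 1.0, atol=1e-6)
        assert not stats.zero_variance.any()

    def test_frozen_stats_applied_to_test_data(self):
        rng = np.random.default_rng(7)
        train = _table(rng.random((40, 5)))
        test = _table(rng.random((10, 5)) + 5.0)
        _, stats = transform_bins(train)
        out, stats2 = transform_bins(test, training_stats=stats)
        assert stats2 is stats
        expected = (np.cbrt(test.values) - stats.mean) / stats.scale
        np.testing.assert_allclose(out.values, expected)
        # test columns are NOT re-centered
        assert np.abs(out.values.mean(axis=0)).min() > 1.0

    def test_zero_variance_bin_flagged_unit_scale(self):
        table = _table([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        out, stats = transform_bins(table)
        assert stats.zero_variance.tolist() == [True, False]
        assert stats.scale[0] == 1.0
        np.testing.assert_allclose(out.values[:, 0], 0.0, atol=1e-12)
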
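"""Pseudo-Voigt line shape, signal fitting and feature processing."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from nephromet.quantify import (PseudoVoigtParams, fit_signal, fit_signals,
                                process_features, pseudo_voigt,
                                quantify_cohort, quantify_panel)
from nephromet.synthetic import GeneratorConfig, generate_spectrum
from nephromet.templates import PANEL_METABOLITES


class TestLineShape:
    def test_gaussian_peak_height(self):
        area, fwhm = 2.0, 0.003
        expected = area * 2 * math.sqrt(math.log(2) / math.pi) / fwhm
        assert pseudo_voigt(0.0, 0.0, area, fwhm, eta=0.0) \
            == pytest.approx(expected, rel=1e-12)

    def test_lorentzian_peak_height(self):
        area, fwhm = 2.0, 0.003
        expected = area * 2 / (math.pi * fwhm)
        assert pseudo_voigt(0.0, 0.0, area, fwhm, eta=1.0) \
            == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("eta", [0.0, 0.3, 0.7, 1.0])
    def test_total_integral_equals_area(self, eta):
        # Lorentzian tails decay as 1/x^2: a wide quadrature window is
        # needed to capture the area to 1e-4 (±5000 FWHM leaves ~1e-4 of a
        # pure Lorentzian outside).
        area, fwhm = 1.7, 0.003
        core, _ = quad(lambda x: pseudo_voigt(x, 0.0, area, fwhm, eta),
                       -50 * fwhm, 50 * fwhm, limit=200)
        tail, _ = quad(lambda x: pseudo_voigt(x, 0.0, area, fwhm, eta),
                       50 * fwhm, 2e4 * fwhm, limit=400)
        assert core + 2 * tail == pytest.approx(area, rel=1e-4)

    @pytest.mark.parametrize("kwargs", [
        {"center": 0, "area": -1, "fwhm": 0.01, "eta": 0.5},
        {"center": 0, "area": 1, "fwhm": 0.0, "eta": 0.5},
        {"center": 0, "area": 1, "fwhm": 0.01, "eta": 1.2},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PseudoVoigtParams(**kwargs)


class TestFitSignal:
    def test_noiseless_roundtrip(self, clean_config, templates):
        truth = 1.37
        sp = generate_spectrum({"alanine": truth}, clean_config)
        q = fit_signal(sp, templates["alanine"])
        assert q.valid
        assert q.params.area == pytest.approx(truth, rel=1e-4)
        assert q.params.center == pytest.approx(templates["alanine"].center,
                                                abs=1e-5)
        assert q.params.fwhm == pytest.approx(templates["alanine"].fwhm,
                                              rel=1e-4)
        assert q.params.eta == pytest.approx(clean_config.eta, abs=1e-4)

    def test_noise_only_window_invalid(self, spectrum_factory, templates):
        rng = np.random.default_rng(0)
        sp = spectrum_factory(lambda ppm: rng.normal(0, 1.0, ppm.size))
        q = fit_signal(sp, templates["alanine"])
        assert not q.valid

    def test_joint_fit_of_overlapping_neighbours(self, clean_config,
                                                 templates):
        """Glucose + glucuronate co-fitted: both areas within 1% at SNR>=100."""
        truth = {"glucose": 3.0, "glucuronate": 2.0}
        cfg = GeneratorConfig(**{**clean_config.__dict__, "noise_sd": 0.005})
        sp = generate_spectrum(truth, cfg)
        results = fit_signals(sp, [templates["glucose"],
                                   templates["glucuronate"]])
        for q in results:
            assert q.valid
            assert q.params.area == pytest.approx(truth[q.metabolite],
                                                  rel=0.01)

    def test_error_rmse_shrinks_with_snr(self, clean_config, templates):
        """Area error decreases as noise falls (bias -> 0 with SNR)."""
        truth = 1.0
        errs = []
        for i, noise in enumerate((0.05, 0.0125, 0.003)):
            sub = []
            for rep in range(4):
                cfg = GeneratorConfig(**{**clean_config.__dict__,
                                         "noise_sd": noise,
                                         "seed": 100 * i + rep})
                sp = generate_spectrum({"lactate": truth}, cfg)
                q = fit_signal(sp, templates["lactate"])
                assert q.valid
                sub.append((q.params.area - truth) ** 2)
            errs.append(math.sqrt(np.mean(sub)))
        assert errs[0] > errs[1] > errs[2]

    def test_window_outside_spectrum_raises(self, spectrum_factory,
                                            templates):
        sp = spectrum_factory(lambda ppm: np.zeros_like(ppm), ppm_stop=1.0)
        with pytest.raises(ValueError):
            fit_signal(sp, templates["hippurate"])

    def test_valid_fits_never_exceed_gof_threshold(self, default_config):
        sp = generate_spectrum(
            {m: 1.0 for m in PANEL_METABOLITES}, default_config)
        for q in quantify_panel(sp, gof_threshold=0.05).values():
            if q.valid:
                assert q.gof <= 0.05


class TestQuantifyPanel:
    def test_full_panel_recovered_within_2_percent(self, clean_config):
        truth = {"alanine": 1.0, "citrate": 4.0, "dma": 0.8, "glucose": 0.6,
                 "glucuronate": 0.5, "hippurate": 3.0, "lactate": 1.2,
                 "paq": 1.5, "trigonelline": 0.7, "urea": 40.0,
                 "creatinine": 8.0}
        # SNR ~200 on the weakest singlet
        cfg = GeneratorConfig(**{**clean_config.__dict__, "noise_sd": 0.3,
                                 "seed": 21})
        quants = quantify_panel(generate_spectrum(truth, cfg))
        assert len(quants) == 11
        for m, q in quants.items():
            assert q.valid, (m, q.reason, q.gof)
            assert q.params.area == pytest.approx(truth[m], rel=0.02), m

    def test_absent_glucuronate_does_not_corrupt_glucose(self, clean_config):
        sp = generate_spectrum({"glucose": 3.0}, clean_config)
        quants = quantify_panel(sp)
        assert quants["glucose"].valid
        assert quants["glucose"].params.area == pytest.approx(3.0, rel=0.01)
        q = quants["glucuronate"]
        assert (not q.valid) or q.params.area < 0.03

    def test_zero_creatinine_makes_sample_unusable(self, clean_config):
        truth = {"alanine": 1.0, "lactate": 1.2, "creatinine": 0.0}
        sp = generate_spectrum(truth, clean_config)
        sp.sample_id = "s0"
        quants = quantify_cohort([sp])
        assert not quants.loc["s0", ("creatinine", "valid")]
        feats, _ = process_features(quants)
        assert feats.loc["s0"].isna().all()


def _quant_table(areas: pd.DataFrame, valid: pd.DataFrame | None = None):
    """Assemble a quant table directly from an area matrix."""
    cols = {}
    for m in areas.columns:
        cols[(m, "area")] = areas[m]
        cols[(m, "gof")] = 0.0
        cols[(m, "valid")] = valid[m] if valid is not None else True
    df = pd.DataFrame(cols, index=areas.index)
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["metabolite", "field"])
    return df.sort_index(axis=1)


class TestProcessFeatures:
    def test_equal_areas_raise_zero_variance_flag(self):
        areas = pd.DataFrame(1.0, index=range(10),
                             columns=list(PANEL_METABOLITES))
        feats, stats = process_features(_quant_table(areas))
        assert set(stats.zero_variance) == set(PANEL_METABOLITES) - {"creatinine"}
        np.testing.assert_allclose(feats.to_numpy(), 0.0, atol=1e-12)

    def test_global_scaling_leaves_features_unchanged(self):
        rng = np.random.default_rng(8)
        areas = pd.DataFrame(
            np.exp(rng.normal(0, 0.4, (30, len(PANEL_METABOLITES)))),
            columns=list(PANEL_METABOLITES))
        a, _ = process_features(_quant_table(areas))
        b, _ = process_features(_quant_table(areas * 7.5))
        pd.testing.assert_frame_equal(a, b)

    def test_creatinine_normalization_induces_half_correlation(self):
        """Independent log-normal areas: log-ratios to the shared creatinine
        denominator are correlated 0.5 (closed-form generator moments)."""
        rng = np.random.default_rng(9)
        n = 2000
        areas = pd.DataFrame(
            np.exp(rng.normal(0, 0.4, (n, len(PANEL_METABOLITES)))),
            columns=list(PANEL_METABOLITES))
        feats, _ = process_features(_quant_table(areas))
        corr = feats.corr().to_numpy()
        off_diag = corr[~np.eye(corr.shape[0], dtype=bool)]
        assert np.allclose(off_diag, 0.5, atol=5 / np.sqrt(n))

    def test_frozen_training_stats_applied_to_test(self):
        rng = np.random.default_rng(10)
        cols = list(PANEL_METABOLITES)
        train = pd.DataFrame(np.exp(rng.normal(0, 0.4, (50, len(cols)))),
                             columns=cols)
        test = pd.DataFrame(np.exp(rng.normal(1.0, 0.4, (20, len(cols)))),
                            columns=cols)
        _, stats = process_features(_quant_table(train))
        feats_test, _ = process_features(_quant_table(test),
                                         training_stats=stats)
        # shifted test distribution must NOT be re-centered
        assert feats_test.mean().abs().mean() > 0.1

    def test_valid_flag_with_nonpositive_area_is_internal_error(self):
        areas = pd.DataFrame(1.0, index=range(3),
                             columns=list(PANEL_METABOLITES))
        areas.loc[0, "lactate"] = 0.0
        with pytest.raises(RuntimeError):
            process_features(_quant_table(areas))
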
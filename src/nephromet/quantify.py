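"""Pseudo-Voigt quantification of the 11-signal metabolite panel.

Each metabolite signal is modelled as a multiplet of pseudo-Voigt
components with fixed splitting pattern and shared width and mixing
fraction, fitted by bounded least squares inside a local window on top of
a local linear background. A normalized residual (goodness of fit) gates
every quantification: values with poor fits are flagged invalid and never
enter downstream modelling.

Glucose and glucuronate resonate in immediately neighbouring positions and
are fitted jointly in a single window so that neither contaminates the
other's area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from nephromet.spectrum import Spectrum
from nephromet.templates import (
    CANDIDATE_METABOLITES,
    SignalTemplate,
    load_templates,
    panel_templates,
)

_SQRT_LN2_PI = math.sqrt(math.log(2.0) / math.pi)


@dataclass(frozen=True)
class PseudoVoigtParams:
    """Parameters of one pseudo-Voigt multiplet.

    ``area`` is the total area of the multiplet (summed over components);
    all components share ``fwhm`` and ``eta``.
    """

    center: float
    area: float
    fwhm: float
    eta: float

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("area must be non-negative")
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if not (0.0 <= self.eta <= 1.0):
            raise ValueError("eta must lie in [0, 1]")


def pseudo_voigt(x, center: float, area: float, fwhm: float, eta: float):
    """Pseudo-Voigt line: area-weighted mix of unit-area Lorentzian/Gaussian.

    value = area * [eta * L(x) + (1 - eta) * G(x)] where L and G are
    unit-area Lorentzian and Gaussian profiles sharing one FWHM.
    """
    x = np.asarray(x, dtype=float)
    u = (x - center) / fwhm
    gauss = (2.0 / fwhm) * _SQRT_LN2_PI * np.exp(-4.0 * math.log(2.0) * u * u)
    lorentz = (2.0 / (math.pi * fwhm)) / (1.0 + 4.0 * u * u)
    return area * (eta * lorentz + (1.0 - eta) * gauss)


def multiplet(x, template: SignalTemplate, center: float, area: float,
              fwhm: float, eta: float):
    """Evaluate a template's multiplet with total area ``area``."""
    y = np.zeros_like(np.asarray(x, dtype=float))
    for off, w in zip(template.offsets, template.weights):
        y += pseudo_voigt(x, center + off, area * w, fwhm, eta)
    return y


@dataclass
class QuantResult:
    """One metabolite's fitted parameters, goodness of fit and validity."""

    metabolite: str
    params: PseudoVoigtParams | None
    gof: float
    valid: bool
    reason: str = ""

    @property
    def area(self) -> float:
        return self.params.area if (self.valid and self.params) else float("nan")


def _initial_area(ppm: np.ndarray, y: np.ndarray, template: SignalTemplate,
                  fwhm: float) -> float:
    lo = template.center + min(template.offsets) - 3 * fwhm
    hi = template.center + max(template.offsets) + 3 * fwhm
    m = (ppm >= lo) & (ppm <= hi)
    if not m.any():
        return 0.0
    base = np.median(y)
    area = float(np.trapezoid(np.clip(y[m] - base, 0, None), ppm[m]))
    return max(area, 0.0)


def fit_signals(spectrum: Spectrum, templates: list[SignalTemplate],
                gof_threshold: float = 0.05,
                center_tol: float = 0.02) -> list[QuantResult]:
    """Jointly fit one or more templates sharing a fit window.

    The model is the sum of the templates' multiplets plus a local linear
    background. Three starting center offsets are tried and the best
    least-squares solution kept (the optimizer is local; the small start
    grid guards against locking onto a neighbouring line).

    Returns one :class:`QuantResult` per template. Non-convergence or a
    normalized RMS residual above ``gof_threshold`` yields ``valid=False``
    rather than an exception; a window outside the spectrum raises.
    """
    win_lo = min(t.fit_window[0] for t in templates)
    win_hi = max(t.fit_window[1] for t in templates)
    if win_lo < spectrum.ppm_start - 1e-9 or win_hi > spectrum.ppm_end + 1e-9:
        raise ValueError(
            f"fit window ({win_lo}, {win_hi}) outside spectrum range "
            f"({spectrum.ppm_start}, {spectrum.ppm_end})")
    ppm, y = spectrum.slice(win_lo, win_hi)
    if ppm.size < 8:
        raise ValueError("fit window contains too few grid points")

    amplitude = float(y.max() - y.min())
    if amplitude <= 0:
        return [QuantResult(t.metabolite, None, 0.0, False, "no_signal")
                for t in templates]

    x_mid = 0.5 * (win_lo + win_hi)
    n_t = len(templates)

    # per-template parameters (dc, area, fwhm, eta) then shared (b0, b1)
    lower, upper, p0 = [], [], []
    for t in templates:
        dc_lo = max(-center_tol, win_lo - (t.center + min(t.offsets)))
        dc_hi = min(center_tol, win_hi - (t.center + max(t.offsets)))
        a0 = _initial_area(ppm, y, t, t.fwhm)
        a_max = max(10.0 * a0, amplitude * (win_hi - win_lo) * 10.0)
        lower += [dc_lo, 0.0, t.fwhm_bounds[0], 0.0]
        upper += [dc_hi, a_max, t.fwhm_bounds[1], 1.0]
        p0 += [0.0, max(a0, 1e-12 * a_max), t.fwhm, 0.5]
    lower += [-np.inf, -np.inf]
    upper += [np.inf, np.inf]
    p0 += [float(np.min(y)), 0.0]
    lower = np.array(lower)
    upper = np.array(upper)
    p0 = np.clip(np.array(p0), lower, upper)

    def model(theta):
        out = np.full_like(ppm, theta[-2]) + theta[-1] * (ppm - x_mid)
        for i, t in enumerate(templates):
            dc, area, fwhm, eta = theta[4 * i:4 * i + 4]
            out += multiplet(ppm, t, t.center + dc, area, fwhm, eta)
        return out

    def residuals(theta):
        return model(theta) - y

    best = None
    span = 0.25 * (win_hi - win_lo)
    for shift in (0.0, -span, span):
        start = p0.copy()
        for i in range(n_t):
            start[4 * i] = np.clip(shift, lower[4 * i], upper[4 * i])
        try:
            sol = least_squares(residuals, start, bounds=(lower, upper),
                                method="trf", max_nfev=400 * (4 * n_t + 2))
        except Exception:  # optimizer failure is a gating event, not an error
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        return [QuantResult(t.metabolite, None, float("inf"), False,
                            "optimizer_failed") for t in templates]

    gof = float(np.sqrt(np.mean(best.fun ** 2)) / amplitude)
    results = []
    for i, t in enumerate(templates):
        dc, area, fwhm, eta = best.x[4 * i:4 * i + 4]
        params = PseudoVoigtParams(center=float(t.center + dc),
                                   area=float(area), fwhm=float(max(fwhm, 1e-12)),
                                   eta=float(np.clip(eta, 0.0, 1.0)))
        reason = ""
        valid = bool(best.status > 0)
        if not valid:
            reason = "non_convergence"
        if gof > gof_threshold:
            valid, reason = False, "gof"
        # parameters pinned at bounds indicate an unreliable fit
        tol_c = 1e-6
        if valid and (dc <= lower[4 * i] + tol_c or dc >= upper[4 * i] - tol_c):
            valid, reason = False, "center_at_bound"
        if valid and (fwhm <= lower[4 * i + 2] * (1 + 1e-6)
                      or fwhm >= upper[4 * i + 2] * (1 - 1e-6)):
            valid, reason = False, "width_at_bound"
        # essentially-zero area: the signal is absent in this sample
        if valid and area * max(pseudo_voigt(0.0, 0.0, 1.0, fwhm, eta), 0.0) \
                < 3.0 * gof * amplitude + 1e-12:
            valid, reason = False, "zero_area"
        results.append(QuantResult(t.metabolite, params, gof, valid, reason))
    return results


def fit_signal(spectrum: Spectrum, template: SignalTemplate,
               gof_threshold: float = 0.05) -> QuantResult:
    """Fit one template; see :func:`fit_signals`."""
    return fit_signals(spectrum, [template], gof_threshold=gof_threshold)[0]


def quantify_panel(spectrum: Spectrum,
                   templates: dict[str, SignalTemplate] | None = None,
                   gof_threshold: float = 0.05) -> dict[str, QuantResult]:
    """Quantify the full metabolite panel on one (QC-passed) spectrum.

    Templates sharing a ``joint_group`` are fitted simultaneously in one
    window; all others are fitted independently. Returns a result per
    metabolite keyed by name.
    """
    templates = panel_templates(templates or load_templates())
    groups: dict[str, list[SignalTemplate]] = {}
    singles: list[SignalTemplate] = []
    for t in templates.values():
        if t.joint_group:
            groups.setdefault(t.joint_group, []).append(t)
        else:
            singles.append(t)

    out: dict[str, QuantResult] = {}
    for t in singles:
        out[t.metabolite] = fit_signal(spectrum, t, gof_threshold)
    for members in groups.values():
        for r in fit_signals(spectrum, members, gof_threshold):
            out[r.metabolite] = r
    return out


def quantify_cohort(spectra: list[Spectrum],
                    templates: dict[str, SignalTemplate] | None = None,
                    gof_threshold: float = 0.05) -> pd.DataFrame:
    """Quantify many spectra; returns a table indexed by sample id.

    Columns are a MultiIndex (metabolite, field) with fields
    ``area``, ``gof``, ``valid``.
    """
    rows = {}
    for sp in spectra:
        quants = quantify_panel(sp, templates, gof_threshold)
        row = {}
        for m, q in quants.items():
            row[(m, "area")] = q.params.area if q.params else np.nan
            row[(m, "gof")] = q.gof
            row[(m, "valid")] = q.valid
        rows[sp.sample_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.columns = pd.MultiIndex.from_tuples(df.columns,
                                           names=["metabolite", "field"])
    return df.sort_index(axis=1)


@dataclass
class FeatureStats:
    """Per-metabolite standardization constants estimated on training data."""

    center: pd.Series
    scale: pd.Series
    zero_variance: list[str] = field(default_factory=list)


def process_features(quants: pd.DataFrame,
                     metabolites: tuple[str, ...] = CANDIDATE_METABOLITES,
                     training_stats: FeatureStats | None = None,
                     ) -> tuple[pd.DataFrame, FeatureStats]:
    """Creatinine-normalize, log-transform, center and scale quantified areas.

    For each candidate metabolite x the feature is
    ``I_x = standardize(log(area_x / area_creatinine))``. Samples whose
    creatinine quantification is invalid are unusable (all features NaN);
    an invalid metabolite quantification leaves that one feature NaN.

    Standardization constants are estimated on the training table and, when
    ``training_stats`` is supplied, applied frozen (test data).
    """
    areas = quants.xs("area", axis=1, level="field")
    valid = quants.xs("valid", axis=1, level="field").astype(bool)

    for m in list(metabolites) + ["creatinine"]:
        bad = valid[m] & ~(areas[m] > 0)
        if bad.any():
            raise RuntimeError(
                f"{m}: non-positive area flagged valid for samples "
                f"{list(areas.index[bad])[:5]} — internal contract violation")

    creat_ok = valid["creatinine"]
    features = pd.DataFrame(index=quants.index, dtype=float)
    for m in metabolites:
        ok = creat_ok & valid[m]
        ratio = areas[m].where(ok) / areas["creatinine"].where(creat_ok)
        features[m] = np.log(ratio)

    if training_stats is None:
        center = features.mean()
        scale = features.std(ddof=0)
        zero_var = [m for m in metabolites
                    if not np.isfinite(scale[m]) or scale[m] < 1e-12]
        scale = scale.where(scale >= 1e-12, 1.0).fillna(1.0)
        center = center.fillna(0.0)
        training_stats = FeatureStats(center=center, scale=scale,
                                      zero_variance=zero_var)
    standardized = (features - training_stats.center) / training_stats.scale
    return standardized, training_stats
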
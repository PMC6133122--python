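"""Synthetic urine-NMR spectra and transplant cohorts.

The generator emulates the statistical structure the downstream analysis
assumes, standing in for clinical data that cannot be shipped:

* urine spectra as sums of metabolite multiplets (pseudo-Voigt line
  shapes) on a smooth polynomial baseline, with a residual-water artifact
  near 4.75 ppm, a TSP reference singlet at 0.0 ppm and i.i.d. Gaussian
  noise;
* a transplant cohort with repeated sampling per patient, biopsy events
  graded on the BANFF scale, and class-dependent log-normal metabolite
  concentrations whose signs match the rejection physiology encoded in the
  final score (citrate and alanine lower, lactate and urea higher during
  rejection).

Every output is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from nephromet.spectrum import Spectrum
from nephromet.templates import PANEL_METABOLITES, SignalTemplate, load_templates
from nephromet.quantify import multiplet, pseudo_voigt

# Class-conditional log-concentration means (natural log, arbitrary area
# units). Controls reflect typical relative urinary signal intensities;
# the case column shifts only the four constellation metabolites, with the
# physiologically expected signs. These are the study conditions of every
# synthetic experiment in the package and are deliberately fixed.
DEFAULT_LOG_MEANS: dict[str, tuple[float, float]] = {
    "alanine":      (0.00, -0.25),
    "citrate":      (1.39,  1.04),
    "dma":          (-0.22, -0.22),
    "glucose":      (-0.51, -0.51),
    "glucuronate":  (-0.69, -0.69),
    "hippurate":    (1.10,  1.10),
    "lactate":      (0.18,  0.53),
    "paq":          (0.41,  0.41),
    "trigonelline": (-0.36, -0.36),
    "urea":         (3.69,  3.89),
    "creatinine":   (2.08,  2.08),
}

DEFAULT_LOG_SDS: dict[str, float] = {m: 0.40 for m in PANEL_METABOLITES}


@dataclass(frozen=True)
class BiopsyPolicy:
    """Probabilities governing biopsy generation."""

    p_biopsy_given_rejection: float = 0.9
    p_biopsy_given_no_rejection: float = 0.1
    p_other_banff: float = 0.05   # chance of an extra BANFF 2/3/5 biopsy


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort and its spectra.

    The same config object drives cohort generation (who is sampled when,
    who rejects, who is biopsied) and spectrum synthesis (line shapes,
    baseline, water artifact, noise). The seed fully determines the output.
    """

    n_patients: int = 60
    samples_per_patient: tuple[int, int] = (4, 12)
    rejection_prevalence: float = 0.3
    biopsy_policy: BiopsyPolicy = field(default_factory=BiopsyPolicy)
    metabolite_log_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LOG_MEANS))
    metabolite_log_sds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_SDS))
    noise_sd: float = 1.0
    baseline_params: tuple[float, ...] = (1.0, 0.2)   # polynomial in ppm
    water_artifact: tuple[float, float] = (50.0, 0.15)  # amplitude, fwhm @4.75
    tsp_area: float = 2.0
    eta: float = 0.5
    ppm_range: tuple[float, float] = (-0.3, 10.0)
    ppm_step: float = 5e-4
    sample_day_range: tuple[int, int] = (5, 400)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        lo, hi = self.samples_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("samples_per_patient must be a valid range")
        if not (0.0 <= self.rejection_prevalence <= 1.0):
            raise ValueError("rejection_prevalence must lie in [0, 1]")
        for m, sd in self.metabolite_log_sds.items():
            if sd <= 0:
                raise ValueError(f"log-sd for {m} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.ppm_step <= 0:
            raise ValueError("ppm_step must be positive")


WATER_CENTER = 4.75
_TX_BASE = date(2020, 1, 1)


@dataclass
class SyntheticCohort:
    """Cohort tables produced by :func:`generate_cohort`.

    ``samples`` — one row per urine sample (sample_id, patient_id, tx_date,
    sample_date, days_post_tx); ``biopsies`` — one row per biopsy event
    (patient_id, biopsy_date, banff, where banff is a '+'-joined category
    string such as ``"4"`` or ``"4+2"``); ``concentrations`` — true
    per-sample metabolite levels; ``labels`` — true per-sample rejection
    status ('case'/'control').
    """

    samples: pd.DataFrame
    biopsies: pd.DataFrame
    concentrations: pd.DataFrame
    labels: pd.Series


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a transplant cohort with biopsies and true concentrations.

    Each patient receives a transplant date and a set of follow-up sample
    days. With probability ``rejection_prevalence`` the patient has one
    acute-rejection episode anchored at one of their sample days; samples
    falling in the 7 days up to the episode day carry case-level metabolite
    concentrations. A BANFF-4 biopsy is generated on the episode day with
    probability ``p_biopsy_given_rejection``; non-rejecting patients get a
    negative (BANFF 1) biopsy with probability
    ``p_biopsy_given_no_rejection``, and any patient may additionally have
    a BANFF 2/3/5 biopsy so both exclusion rules and the strict/extended
    settings are exercised.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.samples_per_patient
    d_lo, d_hi = config.sample_day_range

    sample_rows, biopsy_rows = [], []
    conc_rows, label_rows, sample_ids = [], [], []

    for p in range(config.n_patients):
        pid = f"P{p:04d}"
        tx = _TX_BASE + timedelta(days=int(rng.integers(0, 300)))
        n_s = int(rng.integers(lo, hi + 1))
        days = np.sort(rng.choice(np.arange(d_lo, d_hi + 1),
                                  size=min(n_s, d_hi - d_lo + 1),
                                  replace=False))

        rejector = rng.random() < config.rejection_prevalence
        episode_day = None
        if rejector:
            late = days[days >= 22]
            episode_day = int(rng.choice(late) if late.size else days.max())
            if rng.random() < config.biopsy_policy.p_biopsy_given_rejection:
                banff = "4"
                if rng.random() < config.biopsy_policy.p_other_banff:
                    banff += "+" + str(rng.choice([2, 3, 5]))
                biopsy_rows.append((pid, tx + timedelta(days=episode_day), banff))
        else:
            if rng.random() < config.biopsy_policy.p_biopsy_given_no_rejection:
                bday = int(rng.choice(days))
                biopsy_rows.append((pid, tx + timedelta(days=bday), "1"))
        if rng.random() < config.biopsy_policy.p_other_banff:
            bday = int(rng.choice(days))
            biopsy_rows.append(
                (pid, tx + timedelta(days=bday), str(rng.choice([2, 3, 5]))))

        for k, day in enumerate(days):
            sid = f"{pid}-S{k:03d}"
            is_case = (episode_day is not None
                       and episode_day - 7 <= day <= episode_day)
            sample_rows.append((sid, pid, tx, tx + timedelta(days=int(day)),
                                int(day)))
            col = 1 if is_case else 0
            conc = {m: float(np.exp(rng.normal(
                        config.metabolite_log_means[m][col],
                        config.metabolite_log_sds[m])))
                    for m in PANEL_METABOLITES}
            conc_rows.append(conc)
            label_rows.append("case" if is_case else "control")
            sample_ids.append(sid)

    samples = pd.DataFrame(sample_rows, columns=[
        "sample_id", "patient_id", "tx_date", "sample_date", "days_post_tx"])
    biopsies = pd.DataFrame(biopsy_rows, columns=[
        "patient_id", "biopsy_date", "banff"])
    concentrations = pd.DataFrame(conc_rows, index=sample_ids)
    labels = pd.Series(label_rows, index=sample_ids, name="true_label")
    return SyntheticCohort(samples, biopsies, concentrations, labels)


def generate_spectrum(concentrations, config: GeneratorConfig,
                      sample_id: str = "", batch_id: str = "",
                      rng: np.random.Generator | None = None,
                      templates: dict[str, SignalTemplate] | None = None,
                      ) -> Spectrum:
    """Synthesize one spectrum from per-metabolite concentrations.

    The spectrum is the sum of each metabolite's multiplet (total area
    proportional — here equal — to its concentration), the TSP reference
    singlet at 0.0 ppm, the polynomial baseline, a Gaussian residual-water
    artifact at 4.75 ppm and i.i.d. Gaussian noise.
    """
    templates = templates or load_templates()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    lo, hi = config.ppm_range
    n = int(round((hi - lo) / config.ppm_step)) + 1
    ppm = lo + config.ppm_step * np.arange(n)
    y = np.zeros(n)

    for m, conc in dict(concentrations).items():
        if conc < 0:
            raise ValueError(f"negative concentration for {m}")
        if conc == 0 or m not in templates:
            continue
        t = templates[m]
        y += multiplet(ppm, t, t.center, float(conc), t.fwhm, config.eta)

    if config.tsp_area > 0:
        tsp = templates["tsp"]
        y += multiplet(ppm, tsp, tsp.center, config.tsp_area, tsp.fwhm,
                       config.eta)

    if config.baseline_params:
        y += np.polynomial.polynomial.polyval(ppm,
                                              list(config.baseline_params))
    amp, width = config.water_artifact
    if amp > 0 and width > 0:
        y += amp * np.exp(-4 * np.log(2) * ((ppm - WATER_CENTER) / width) ** 2)
    if config.noise_sd > 0:
        y += rng.normal(0.0, config.noise_sd, size=n)

    return Spectrum(ppm_start=float(ppm[0]), ppm_step=config.ppm_step,
                    intensities=y, sample_id=sample_id, batch_id=batch_id)


def generate_cohort_spectra(cohort: SyntheticCohort, config: GeneratorConfig,
                            ) -> list[Spectrum]:
    """One spectrum per cohort sample, deterministically seeded per sample."""
    templates = load_templates()
    root = np.random.default_rng(config.seed)
    streams = root.spawn(len(cohort.concentrations))
    spectra = []
    for (sid, conc), rng in zip(cohort.concentrations.iterrows(), streams):
        spectra.append(generate_spectrum(conc.to_dict(), config,
                                         sample_id=sid, rng=rng,
                                         templates=templates))
    return spectra


def generate_feature_table(n: int, model, seed: int
                           ) -> tuple[pd.DataFrame, np.ndarray]:
    """Standard-normal features with labels drawn from a rejection-score model.

    Features I_alanine, I_citrate, I_lactate, I_urea are i.i.d. standard
    normal; the binary label is Bernoulli(Score/100) where Score is the
    model's logistic score. Used for parameter-recovery experiments: an
    unpenalized logistic fit to this table estimates the model's printed
    coefficients.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    order = list(model.feature_order)
    X = rng.standard_normal((n, len(order)))
    beta = np.array([model.coefficients[f] for f in order])
    omega = model.intercept + X @ beta
    p = 1.0 / (1.0 + np.exp(-omega))
    y = (rng.random(n) < p).astype(int)
    features = pd.DataFrame(X, columns=order)
    return features, y
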
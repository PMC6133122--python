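# Methods

This note records the models, the defaults and the genuinely open design
choices in `nephromet`, and what the synthetic experiments do and do not
establish about real data.

## Spectra and preprocessing

A spectrum is a 1D intensity vector on a uniform ppm grid (stored
ascending; default grid −0.3 to 10.0 ppm at 5·10⁻⁴ ppm per point). Spectra
are assumed phase-corrected in absorption mode by the acquisition software;
the package performs no phase correction.

**Referencing.** The TSP singlet apex (search window ±0.2 ppm, required to
rise ≥5 robust noise levels above the window median) is located with
parabolic sub-grid refinement and the axis shifted so it sits at 0.0 ppm.
Referencing an already-referenced spectrum is the identity to within half a
grid step. A spectrum without a usable reference raises and is excluded.

**Baseline.** Asymmetric-least-squares (Whittaker) smoothing with stiffness
λ = 10⁸ and asymmetry p = 0.05 (10 reweighting iterations). λ was chosen so
the baseline follows trends slower than ~1 ppm while ignoring peaks of a
few mHz width; p = 0.05 places the baseline near the center of the noise
band rather than its lower envelope (an extreme p leaves a positive
residual offset of roughly two noise SDs, which would then fail QC). The
estimator is exactly additive: correcting y + c equals correcting y. It
removes ~0.2% of the area of sharp peaks; quantification is tolerant of
this because each fit window carries its own local linear background.

**Quality control.** Configurable checks on (a) mean offset and linear
slope of the residual baseline in two signal-free windows (9.55–9.95 and
0.25–0.45 ppm, deliberately away from grid edges where the smoother bends),
and (b) TSP position (|δ| ≤ 0.005 ppm), width (1–8 mHz, i.e. 0.001–0.008
ppm) and left/right half-width asymmetry (≤0.3). A report lists every
failed check; `passed` is true iff no reasons. Which regions the original
instrument software inspected is unknown; these defaults are project
choices.

**Binning.** The analysis region 0.716–9.510 ppm is tiled with equal
0.022-ppm bins and bins overlapping the residual-water region 4.5–5.0 ppm
are dropped, leaving exactly 172 + 205 = 377 bins. The exact range and
width behind the 377-bin layout of the original study are not recoverable;
this layout is a project constant, asserted by a configuration-conformance
test rather than hard-coded. Bin values are trapezoidal integrals with
interpolated bin edges. Total-integral normalization divides each row by
its sum (zero-integral samples are flagged invalid). The transform is the
*signed* real cube root (bins can go slightly negative after baseline
removal) followed by autoscaling; autoscaling constants are estimated on
training data only and applied frozen to test data — required for an
honest test-set AUC. Zero-variance bins receive unit scale and a flag.

## Quantification

Each panel signal is a multiplet of pseudo-Voigt components

    pV(x) = area · [η·L(x; c, f) + (1−η)·G(x; c, f)]

with unit-area Lorentzian L and Gaussian G sharing one FWHM f, fixed
literature splitting patterns, and one (center-shift, area, f, η) tuple per
metabolite plus a local linear background per window. Fitting is bounded
trust-region least squares from three starting center offsets (deterministic
given inputs). The chemical shifts and J-splittings shipped in
`nephromet/data/signal_templates.json` are literature-standard urine values
(alanine doublet 1.48 ppm, lactate doublet 1.33 ppm, citrate AB system
2.53–2.67 ppm, creatinine singlet 3.05 ppm, urea broad singlet 5.78 ppm,
…); the signals quantified in the original study were never published.
Glucose (5.233 ppm) and glucuronate (5.275 ppm) are immediate neighbours
and are always fitted jointly in one window.

Goodness of fit is the RMS residual normalized by the in-window amplitude;
the default gate is 0.05 (no published value exists — configurable). A fit
is additionally invalidated by non-convergence, center or width pinned at
its bounds, or an essentially-zero area. Invalid quantifications propagate
as missing features; an invalid creatinine makes the whole sample unusable.

Features are I_x = standardize(ln(area_x / area_creatinine)) — creatinine
normalization compensates urine dilution (and makes every I_x exactly
invariant to global spectrum scaling), the natural log symmetrizes the
intensity distribution (any log base is absorbed by standardization), and
centering/scaling constants are again training-only.

## Cohort labeling

Biopsies are graded BANFF 1 (negative), 2 (antibody-mediated), 3
(borderline), 4 (acute cellular rejection), 5 (chronic); one biopsy may
report several categories. A sample is attached to a biopsy taken 0–7 days
after it (inclusive at both ends; the nearest wins). Attached samples are
case if BANFF 4 is present (also when reported together with 2/3/5),
control if the biopsy is exactly BANFF 1, excluded otherwise. Unattached
training samples are controls when their patient was never biopsied or had
only negative biopsies, excluded otherwise; unattached test samples are
excluded under the *strict* setting and controls under the *extended*
setting. The late phase is day ≥ 15 after transplantation with transplant
day = 0 (the ≥15 convention is adopted where the two plausible readings of
"at least 14 days" conflict), and only late-phase samples enter modelling.

## Feature selection (bin phase)

R repeats of stratified k-fold cross-validation (defaults R = 20, k = 5)
each fit a random forest on the training folds and score every bin by
held-out permutation importance (more stable than impurity importance for
correlated bins); scores are aggregated by the median and bins at or below
the importance threshold (default 0) are eliminated, iterating to a stable
set (≤3 iterations). The original procedure's repeat counts and cutoffs
were not published; these are declared defaults. The original *visual*
assessment of candidate bins is replaced by quantitative flags — low
signal-to-noise, peak apex straddling a bin edge, baseline-dominated
integral — each logged with its value so a human can review the decisions.

## Model search, filtering and the final score

All Σᵢ₌₁⁵ C(10, i) = 637 subsets of the ten candidates are fitted as
unpenalized logistic regressions (maximum likelihood; perfect separation is
flagged, not silently penalized). Training performance is patient-grouped
repeated k-fold cross-validated AUC (defaults 5 folds; grouping keeps a
patient's repeated samples in one fold to prevent leakage — whether the
original cross-validation was grouped is not stated, grouping is the safe
choice). Each candidate uses its complete cases, so the usable n varies
with the subset, mirroring quantification failures. A random forest can be
run through identical folds as a parsimony check; on linear ground truth it
does not beat the logistic model.

The filtering cascade is a declarative, ordered rule list with a full audit
trail (`FilterTrace` per stage; in-counts, out-counts and survivor sets
reconcile by construction and by test): keep cv-AUC ≥ 0.75 on training,
keep test AUC ≥ 0.70 per setting (both inclusive), then the curation
judgment calls — exclude trigonelline (a coffee-intake marker), require
lactate, prefer alanine over the correlated hippurate, drop DMA (negligible
paired ΔAUC), drop glucose (glucosuria interference) and glucuronate
(xenobiotic confounding). Paired ΔAUC utilities compare exactly matched
model pairs (S vs S∪{f}, or a↔b swaps) and report the median absolute
difference. The strict/extended survivor lists are intersected by
feature-set identity.

ROC curves use the rank/trapezoid AUC (identical to the Mann–Whitney
U-statistic, half credit for ties) with a stratified-bootstrap 95% CI
(default 2000 draws, cases and controls resampled separately).

The final score is Score = 100·sigmoid(ω) with the published coefficients
as package defaults. No classification cutoff is shipped — the score is
reported as a continuous quantity. The original training cohort's
standardization constants were never published, so the exact published
model cannot be applied to new raw data; model files produced by a training
run carry their own constants, and this limitation is inherent.

## Synthetic data: what it does and does not show

The generator draws, per patient, a transplant date, 4–12 follow-up sample
days (days 5–400), a rejection episode with probability 0.3 anchored at one
sample day, a BANFF-4 biopsy on the episode day with probability 0.9 (a
negative biopsy with probability 0.1 for non-rejectors, plus occasional
BANFF 2/3/5 events so the exclusion rules and both test settings are
populated). Metabolite concentrations are log-normal — guaranteeing
positivity and making the log transform natural — with class shifts only in
the four constellation metabolites, signed as in the rejection physiology
(alanine −0.25, citrate −0.35, lactate +0.35, urea +0.20 on the natural-log
scale, common SD 0.4): moderate effects yielding single-feature AUCs around
0.65–0.75 and a multivariate AUC near 0.8. Spectra are sums of the template
multiplets plus a TSP singlet (area 2), a linear baseline (1.0 + 0.2·ppm), a
Gaussian residual-water artifact at 4.75 ppm (amplitude 50, FWHM 0.15 ppm)
and i.i.d. Gaussian noise (SD 1 ≈ 1/150 of a unit-area component height).
No published distributional description of real urinary levels exists;
these are stated assumptions, not estimates of any study population.

Deliberately not emulated: J-coupling fine structure beyond the fixed
splittings, pH-dependent shift drift, peak-shape distortions, between-run
drift, and real biological covariance between metabolites. Passing tests
therefore demonstrate that the *pipeline logic* is correct and that
parameters are recovered under the stated model — not that the published
AUCs would reproduce on clinical data, which are not available.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately compact problem sizes chosen as
reasonable desk-scale experiments: coefficient recovery at n = 50,000
(Monte-Carlo SE ≈ 0.02 per coefficient, so the ±0.05 check is ≈ 2.5 SEs);
end-to-end runs at 16–24 patients with 3–6 samples each; the core-vs-noise
ranking over 20 seeds at 60 patients using quantification-level features;
random-forest selection checks with 2 × 3-fold repeats and 100-tree
forests. Tolerances follow the arithmetic: noiseless pseudo-Voigt
round-trips hold to 10⁻⁴ relative (optimizer tolerance), normalization
identities to 10⁻⁹, autoscaling to 10⁻⁶. One analytic caveat: a pseudo-Voigt
integrated over ±50 FWHM captures the full area only up to the Lorentzian
tail mass (≈0.64% for η = 1); area equality to 10⁻⁴ requires quadrature out
to ~10⁴ FWHM, and the tests integrate accordingly. Ties in fold assignment,
optimizer starts and bootstrap draws are all seeded; every public function
with randomness takes an explicit seed and is reproducible from it.
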
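"""End-to-end orchestration on synthetic cohorts.

Glues the full chain together — simulate, reference, baseline-correct,
quality-control, quantify, label, search, filter, score — with the
train/test split done at the patient level (the test patients' samples are
labeled under both the strict and the extended setting). Primarily used by
the CLI and the integration tests; each stage remains independently
callable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nephromet import filtering, labeling, modelsearch, preprocess, quantify, scoring
from nephromet.synthetic import GeneratorConfig, SyntheticCohort, \
    generate_cohort, generate_cohort_spectra


@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    qc_failed: list[str]
    quants: pd.DataFrame
    train_features: pd.DataFrame
    train_labels: pd.Series
    test_features: dict
    search: modelsearch.SearchResults
    survivors: list
    traces: list
    final_results: modelsearch.PanelLogisticResults | None
    scores: pd.DataFrame
    roc: modelsearch.ROCResult | None


def _binary(labels: pd.Series) -> pd.Series:
    return (labels == "case").astype(int)


def run_pipeline(config: GeneratorConfig | None = None,
                 seed: int = 0,
                 test_fraction: float = 0.3,
                 max_size: int = 5,
                 folds: int = 5,
                 repeats: int = 2,
                 rules: list | None = None,
                 gof_threshold: float = 0.05) -> PipelineResult:
    """Run the full synthetic pipeline; deterministic for a given seed."""
    if config is None:
        config = GeneratorConfig(seed=seed)
    cohort = generate_cohort(config)
    spectra = generate_cohort_spectra(cohort, config)

    processed, qc_failed = [], []
    for sp in spectra:
        try:
            sp = preprocess.reference_to_tsp(sp)
        except preprocess.ReferencingError:
            qc_failed.append(sp.sample_id)
            continue
        sp = preprocess.correct_baseline(sp)
        report = preprocess.qc_filter(sp)
        if not report.passed:
            qc_failed.append(sp.sample_id)
            continue
        processed.append(sp)

    quants = quantify.quantify_cohort(processed, gof_threshold=gof_threshold)

    # patient-level train/test split
    rng = np.random.default_rng(seed)
    patients = cohort.samples["patient_id"].unique()
    perm = rng.permutation(patients)
    n_test = max(1, int(round(test_fraction * patients.size)))
    test_patients = set(perm[:n_test])
    samples = cohort.samples.set_index("sample_id")
    is_test = samples["patient_id"].isin(test_patients)

    def _labeled(mode: str, subset_ids) -> pd.DataFrame:
        sub = cohort.samples[cohort.samples["sample_id"].isin(subset_ids)]
        lab = labeling.label_cohort(sub, cohort.biopsies, mode=mode)
        lab = labeling.phase_filter(lab)
        return lab[lab["label"] != "excluded"]

    train_ids = samples.index[~is_test & samples.index.isin(quants.index)]
    test_ids = samples.index[is_test & samples.index.isin(quants.index)]

    lab_train = _labeled("training", train_ids)
    lab_strict = _labeled("test_strict", test_ids)
    lab_ext = _labeled("test_extended", test_ids)

    ids = quants.index.intersection(lab_train["sample_id"])
    train_feat, stats = quantify.process_features(quants.loc[ids])
    lab_train = lab_train.set_index("sample_id").loc[ids]
    y_train = _binary(lab_train["label"])

    test_sets = {}
    test_features = {}
    for name, lab in (("strict", lab_strict), ("extended", lab_ext)):
        ids = quants.index.intersection(lab["sample_id"])
        if len(ids) == 0:
            continue
        feat, _ = quantify.process_features(quants.loc[ids],
                                            training_stats=stats)
        yl = _binary(lab.set_index("sample_id").loc[ids, "label"])
        test_features[name] = (feat, yl)
        if yl.nunique() == 2:
            test_sets[name] = (feat, yl.to_numpy())

    search = modelsearch.ExhaustiveSearch(
        train_feat, y_train.to_numpy(),
        groups=lab_train["patient_id"].to_numpy(),
    ).fit(max_size=max_size, folds=folds, repeats=repeats, seed=seed,
          test_sets=test_sets)

    survivors, traces = filtering.run_cascade(search.candidates, rules)

    # fit the winning constellation (best surviving cv AUC; fall back to the
    # published four-metabolite feature set when the cascade empties)
    final_results = None
    if survivors:
        best = max(survivors, key=lambda c: (c.cv_auc_train
                                             if np.isfinite(c.cv_auc_train)
                                             else -1))
        feats = list(best.features)
    else:
        feats = [f for f in scoring.FEATURE_ORDER
                 if f in train_feat.columns]
    rows = train_feat[feats].dropna()
    if len(rows) and y_train.loc[rows.index].nunique() == 2:
        final_results = modelsearch.fit_logistic(
            rows, y_train.loc[rows.index].to_numpy())

    if final_results is not None:
        model = scoring.FinalModel(
            intercept=float(final_results.params["const"]),
            coefficients={f: float(final_results.params[f]) for f in feats},
            feature_order=tuple(feats))
    else:
        model = scoring.FinalModel()

    # score the strict test set when it carries both classes, else fall
    # back to extended, else the training cohort
    score_src = (train_feat, y_train)
    for name in ("strict", "extended"):
        if name in test_features and test_features[name][1].nunique() == 2:
            score_src = test_features[name]
            break
    scores, roc = scoring.score_cohort(score_src[0], model,
                                       labels=score_src[1], seed=seed)

    return PipelineResult(cohort=cohort, qc_failed=qc_failed, quants=quants,
                          train_features=train_feat, train_labels=y_train,
                          test_features=test_features, search=search,
                          survivors=survivors, traces=traces,
                          final_results=final_results, scores=scores, roc=roc)
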
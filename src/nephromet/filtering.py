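"""The model-filtering cascade.

Automated stages drop candidates below AUC thresholds on the training and
test cohorts; "manual" stages encode the judgment calls of model curation
(exclude a diet-confounded metabolite, require or prefer a feature after a
paired AUC comparison) as a declarative, ordered and fully audited rule
list. Every stage emits a :class:`FilterTrace` so the cascade reconciles
end to end: no candidate disappears without a recorded rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nephromet.modelsearch import ModelCandidate


@dataclass
class FilterTrace:
    """Audit record of one filtering stage."""

    stage: str
    rule: str
    candidates_in: int
    candidates_out: int
    survivors: list[frozenset] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.candidates_out > self.candidates_in:
            raise ValueError("a filter cannot create candidates")
        if self.candidates_out != len(self.survivors):
            raise ValueError("survivor list inconsistent with out-count")


def _trace(stage: str, rule: str, before: list[ModelCandidate],
           after: list[ModelCandidate]) -> FilterTrace:
    return FilterTrace(stage=stage, rule=rule,
                       candidates_in=len(before), candidates_out=len(after),
                       survivors=[c.feature_set for c in after])


def filter_by_train_auc(candidates: list[ModelCandidate],
                        threshold: float = 0.75
                        ) -> tuple[list[ModelCandidate], FilterTrace]:
    """Keep candidates with training-cohort cross-validated AUC >= threshold.

    The comparison is inclusive; NaN AUCs (failed fits) are dropped.
    """
    survivors = [c for c in candidates
                 if np.isfinite(c.cv_auc_train) and c.cv_auc_train >= threshold]
    return survivors, _trace("train_auc", f"cv_auc_train >= {threshold}",
                             candidates, survivors)


def filter_by_test_auc(candidates: list[ModelCandidate], setting: str,
                       threshold: float = 0.70
                       ) -> tuple[list[ModelCandidate], FilterTrace]:
    """Keep candidates with test AUC >= threshold under one setting.

    A candidate without a test AUC for the setting is dropped (reasoned in
    the trace rule); the comparison is inclusive.
    """
    survivors = []
    for c in candidates:
        auc = c.auc(setting)
        if np.isfinite(auc) and auc >= threshold:
            survivors.append(c)
    return survivors, _trace(f"test_auc[{setting}]",
                             f"auc_{setting} >= {threshold} (missing -> drop)",
                             candidates, survivors)


def exclude_feature(candidates: list[ModelCandidate], feature: str,
                    known_features: set | None = None
                    ) -> tuple[list[ModelCandidate], FilterTrace]:
    """Remove every candidate whose feature set contains ``feature``."""
    if known_features is not None and feature not in known_features:
        raise ValueError(f"unknown feature: {feature!r}")
    survivors = [c for c in candidates if feature not in c.feature_set]
    return survivors, _trace(f"exclude[{feature}]",
                             f"{feature} not in features",
                             candidates, survivors)


def require_feature(candidates: list[ModelCandidate], feature: str
                    ) -> tuple[list[ModelCandidate], FilterTrace]:
    """Keep only candidates whose feature set contains ``feature``."""
    survivors = [c for c in candidates if feature in c.feature_set]
    return survivors, _trace(f"require[{feature}]",
                             f"{feature} in features",
                             candidates, survivors)


def paired_delta_auc(candidates: list[ModelCandidate], feature: str,
                     setting: str) -> tuple[pd.DataFrame, float]:
    """AUC effect of adding one feature, over exactly matched model pairs.

    Pairs (S, S + {feature}) are matched by feature-set identity;
    dAUC = AUC(with) - AUC(without) under ``setting``. Returns the pair
    table and the median absolute difference (NaN when no pairs exist).
    """
    by_set = {c.feature_set: c for c in candidates}
    rows = []
    for fs, c in by_set.items():
        if feature in fs:
            continue
        partner = by_set.get(fs | {feature})
        if partner is None:
            continue
        rows.append({"without": "+".join(sorted(fs)) or "(none)",
                     "auc_without": c.auc(setting),
                     "auc_with": partner.auc(setting),
                     "delta": partner.auc(setting) - c.auc(setting)})
    pairs = pd.DataFrame(rows)
    median_abs = float(pairs["delta"].abs().median()) if len(pairs) else float("nan")
    return pairs, median_abs


def paired_swap_auc(candidates: list[ModelCandidate], feature_a: str,
                    feature_b: str, setting: str
                    ) -> tuple[pd.DataFrame, float]:
    """AUC effect of substituting feature_a for feature_b in matched pairs.

    Pairs differ only by the a <-> b swap; dAUC = AUC(a-version) -
    AUC(b-version) under ``setting``.
    """
    by_set = {c.feature_set: c for c in candidates}
    rows = []
    for fs, c in by_set.items():
        if feature_a not in fs or feature_b in fs:
            continue
        partner = by_set.get((fs - {feature_a}) | {feature_b})
        if partner is None:
            continue
        rows.append({"a_version": "+".join(sorted(fs)),
                     "auc_a": c.auc(setting),
                     "auc_b": partner.auc(setting),
                     "delta": c.auc(setting) - partner.auc(setting)})
    pairs = pd.DataFrame(rows)
    median_abs = float(pairs["delta"].abs().median()) if len(pairs) else float("nan")
    return pairs, median_abs


def intersect_settings(strict_survivors: list[ModelCandidate],
                       extended_survivors: list[ModelCandidate]
                       ) -> list[ModelCandidate]:
    """Candidates surviving both settings, matched by feature-set identity."""
    extended_sets = {c.feature_set for c in extended_survivors}
    return [c for c in strict_survivors if c.feature_set in extended_sets]


#: Default cascade mirroring the published curation sequence: AUC gates,
#: exclusion of the coffee-confounded metabolite, requiring lactate,
#: preferring alanine over its correlated alternative hippurate, dropping
#: the negligible-gain DMA, and dropping glucose (glucosuria interference)
#: and glucuronate (xenobiotic confounding).
DEFAULT_RULES: list[dict] = [
    {"op": "train_auc", "threshold": 0.75},
    {"op": "test_auc", "setting": "strict", "threshold": 0.70},
    {"op": "test_auc", "setting": "extended", "threshold": 0.70},
    {"op": "exclude", "feature": "trigonelline"},
    {"op": "require", "feature": "lactate"},
    {"op": "exclude", "feature": "hippurate"},
    {"op": "exclude", "feature": "dma"},
    {"op": "exclude", "feature": "glucose"},
    {"op": "exclude", "feature": "glucuronate"},
]


def run_cascade(candidates: list[ModelCandidate],
                rules: list[dict] | None = None
                ) -> tuple[list[ModelCandidate], list[FilterTrace]]:
    """Apply an ordered rule list, returning survivors and the full audit."""
    rules = DEFAULT_RULES if rules is None else rules
    current = list(candidates)
    traces: list[FilterTrace] = []
    for rule in rules:
        op = rule["op"]
        if op == "train_auc":
            current, tr = filter_by_train_auc(current, rule["threshold"])
        elif op == "test_auc":
            current, tr = filter_by_test_auc(current, rule["setting"],
                                             rule["threshold"])
        elif op == "exclude":
            current, tr = exclude_feature(current, rule["feature"])
        elif op == "require":
            current, tr = require_feature(current, rule["feature"])
        else:
            raise ValueError(f"unknown rule op: {op!r}")
        traces.append(tr)
    return current, traces
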
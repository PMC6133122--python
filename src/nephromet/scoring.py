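"""The metabolite rejection score.

The final model combines four standardized, creatinine-normalized,
log-transformed urinary metabolite intensities into a linear predictor

    omega = beta_0 + beta_ala * I_alanine + beta_cit * I_citrate
                  + beta_lac * I_lactate + beta_urea * I_urea

and reports Score = 100 / (1 + exp(-omega)), a value in (0, 100) that
rises with lactate and urea and falls with alanine and citrate. The
published coefficients are shipped as the package default; the
standardization constants of the original training cohort were never
published, so applying the published coefficients to new data requires
standardization constants from one's own training run (carried in the
model file).

No decision cutoff is shipped: the score is reported as a continuous
quantity and any classification threshold is the user's choice.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from nephromet.modelsearch import ROCResult, roc_auc

PUBLISHED_INTERCEPT = -3.0048615
PUBLISHED_COEFFICIENTS = {
    "alanine": -0.2527461,
    "citrate": -0.8224731,
    "lactate": 0.9502339,
    "urea": 0.2529190,
}
FEATURE_ORDER = ("alanine", "citrate", "lactate", "urea")


@dataclass(frozen=True)
class FinalModel:
    """A rejection-score model: intercept, slopes and standardization.

    The default instance carries the published constants. ``standardization``
    maps each feature to (center, scale) from the training run that produced
    the model file; ``None`` means the inputs are already standardized.
    """

    intercept: float = PUBLISHED_INTERCEPT
    coefficients: dict = field(
        default_factory=lambda: dict(PUBLISHED_COEFFICIENTS))
    feature_order: tuple = FEATURE_ORDER
    standardization: dict | None = None

    def __post_init__(self) -> None:
        missing = set(self.feature_order) - set(self.coefficients)
        if missing:
            raise ValueError(f"coefficients missing for: {missing}")

    def omega(self, features) -> float:
        """Linear predictor for one sample (mapping feature -> I_x)."""
        z = self.intercept
        for f in self.feature_order:
            x = float(features[f])
            if self.standardization is not None:
                c, s = self.standardization[f]
                x = (x - c) / s
            z += self.coefficients[f] * x
        return z

    @classmethod
    def published(cls) -> "FinalModel":
        """The shipped published model file."""
        text = resources.files("nephromet.data").joinpath(
            "final_model.json").read_text()
        return cls.from_json_text(text)

    @classmethod
    def from_json_text(cls, text: str) -> "FinalModel":
        doc = json.loads(text)
        std = doc.get("standardization")
        if std is not None:
            std = {k: tuple(v) for k, v in std.items()}
        return cls(intercept=float(doc["intercept"]),
                   coefficients={k: float(v)
                                 for k, v in doc["coefficients"].items()},
                   feature_order=tuple(doc["feature_order"]),
                   standardization=std)

    @classmethod
    def from_json(cls, path) -> "FinalModel":
        with open(path) as fh:
            return cls.from_json_text(fh.read())

    def to_json(self, path) -> None:
        doc = {"intercept": self.intercept,
               "coefficients": self.coefficients,
               "feature_order": list(self.feature_order),
               "standardization": (None if self.standardization is None else
                                   {k: list(v) for k, v in
                                    self.standardization.items()})}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)


@dataclass
class RejectionScore:
    """A scored sample; score = 100 / (1 + exp(-omega)), in (0, 100)."""

    score: float
    omega: float
    inputs_valid: bool
    missing_features: list = field(default_factory=list)


def _sigmoid100(omega: float) -> float:
    return 100.0 / (1.0 + math.exp(-omega))


def compute_score(features, model: FinalModel | None = None) -> RejectionScore:
    """Score one sample from its processed features.

    Any required feature that is missing or non-finite makes the result
    invalid — a score is never silently imputed.
    """
    model = model or FinalModel()
    missing = [f for f in model.feature_order
               if f not in features or not np.isfinite(float(features[f]))]
    if missing:
        return RejectionScore(score=float("nan"), omega=float("nan"),
                              inputs_valid=False, missing_features=missing)
    omega = model.omega(features)
    return RejectionScore(score=_sigmoid100(omega), omega=omega,
                          inputs_valid=True)


def score_cohort(features: pd.DataFrame, model: FinalModel | None = None,
                 labels=None, seed: int = 0
                 ) -> tuple[pd.DataFrame, ROCResult | None]:
    """Score every sample of a processed feature table.

    Returns (scores table, ROCResult or None). The ROC is computed over the
    valid-score samples when ``labels`` is given. Raises when no sample is
    scorable.
    """
    model = model or FinalModel()
    rows = []
    for sid, row in features.iterrows():
        rs = compute_score(row, model)
        rows.append({"sample_id": sid, "omega": rs.omega, "score": rs.score,
                     "inputs_valid": rs.inputs_valid})
    out = pd.DataFrame(rows).set_index("sample_id")
    if not out["inputs_valid"].any():
        raise ValueError("no sample has a complete, valid feature set")
    roc = None
    if labels is not None:
        lab = pd.Series(np.asarray(labels, dtype=int), index=features.index)
        mask = out["inputs_valid"]
        roc = roc_auc(out.loc[mask, "score"], lab[mask], seed=seed)
    return out, roc
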
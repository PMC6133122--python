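"""Case/control labeling of transplant urine samples.

Training rule set: a sample taken up to 7 days before a biopsy (including
the biopsy day) is attached to that biopsy and labeled by its BANFF
outcome — case for acute cellular rejection (BANFF 4, any grade, including
when reported together with other categories), control for a negative
biopsy (BANFF 1 only), excluded for antibody-mediated rejection (BANFF 2),
borderline changes (BANFF 3) or chronic rejection (BANFF 5) without a
concurrent BANFF 4. Samples not attached to any biopsy are controls when
the patient was never biopsied or all their biopsies were negative, and
excluded otherwise.

Test rule set: biopsy-attached samples are labeled as above; unattached
samples are excluded in the *strict* setting and counted as controls in
the *extended* setting.

Samples earlier than day 15 after transplantation (transplant day = day 0)
belong to the early phase and are removed by :func:`phase_filter` before
modelling.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import pandas as pd

BANFF_CATEGORIES = frozenset({1, 2, 3, 4, 5})
BIOPSY_WINDOW_DAYS = 7     # sample up to 7 days before biopsy, inclusive
LATE_PHASE_MIN_DAY = 15    # late phase: day >= 15 post transplant


@dataclass(frozen=True)
class BiopsyRecord:
    """One biopsy event; ``banff`` may hold several concurrent categories."""

    patient_id: str
    biopsy_date: date
    banff: frozenset

    def __post_init__(self) -> None:
        if not self.banff or not self.banff <= BANFF_CATEGORIES:
            raise ValueError(f"invalid BANFF categories: {set(self.banff)}")


def parse_banff(value) -> frozenset:
    """Parse a BANFF category spec like ``4``, ``"4"`` or ``"4+2"``."""
    if isinstance(value, frozenset):
        return value
    if isinstance(value, (int, float)):
        return frozenset({int(value)})
    return frozenset(int(tok) for tok in str(value).split("+"))


@dataclass
class LabeledSample:
    sample_id: str
    patient_id: str
    sample_date: date
    days_post_tx: int
    label: str                    # case | control | excluded
    phase: str                    # early | late
    basis: str                    # biopsy | no_biopsy_control | none
    setting: str                  # training | test_strict | test_extended

    def __post_init__(self) -> None:
        if self.label == "case" and self.basis != "biopsy":
            raise ValueError("a case label requires a biopsy basis")


def _linked_biopsy(sample_date: date, biopsies: list[BiopsyRecord]
                   ) -> BiopsyRecord | None:
    """The biopsy a sample is attached to, if any.

    Eligible biopsies lie 0..7 days after the sample. When several are
    eligible the nearest wins; equal distance is impossible for distinct
    dates, so any residual tie (duplicate dates) is broken toward the later
    record order.
    """
    eligible = []
    for b in biopsies:
        delta = (b.biopsy_date - sample_date).days
        if 0 <= delta <= BIOPSY_WINDOW_DAYS:
            eligible.append((delta, b))
    if not eligible:
        return None
    eligible.sort(key=lambda t: t[0])
    return eligible[0][1]


def _banff_label(banff: frozenset) -> str:
    if 4 in banff:
        return "case"
    if banff == {1}:
        return "control"
    return "excluded"


def _phase(days_post_tx: int) -> str:
    return "late" if days_post_tx >= LATE_PHASE_MIN_DAY else "early"


def _sample_fields(sample) -> tuple[str, str, date, date]:
    sid = sample["sample_id"]
    pid = sample["patient_id"]
    tx = sample["tx_date"]
    sdate = sample["sample_date"]
    if sdate < tx:
        raise ValueError(f"{sid}: sample date precedes transplant date")
    return sid, pid, tx, sdate


def label_training(sample, biopsies: list[BiopsyRecord]) -> LabeledSample:
    """Label one training-cohort sample given its patient's biopsies."""
    sid, pid, tx, sdate = _sample_fields(sample)
    days = (sdate - tx).days
    linked = _linked_biopsy(sdate, biopsies)
    if linked is not None:
        label, basis = _banff_label(linked.banff), "biopsy"
    elif not biopsies or all(b.banff == {1} for b in biopsies):
        label, basis = "control", "no_biopsy_control"
    else:
        label, basis = "excluded", "none"
    return LabeledSample(sid, pid, sdate, days, label, _phase(days), basis,
                         "training")


def label_test(sample, biopsies: list[BiopsyRecord], setting: str
               ) -> LabeledSample:
    """Label one test-cohort sample under the strict or extended setting."""
    if setting not in ("strict", "extended"):
        raise ValueError(f"unknown setting: {setting!r}")
    sid, pid, tx, sdate = _sample_fields(sample)
    days = (sdate - tx).days
    linked = _linked_biopsy(sdate, biopsies)
    if linked is not None:
        label, basis = _banff_label(linked.banff), "biopsy"
    elif setting == "extended":
        label, basis = "control", "no_biopsy_control"
    else:
        label, basis = "excluded", "none"
    return LabeledSample(sid, pid, sdate, days, label, _phase(days), basis,
                         f"test_{setting}")


def _biopsy_records(biopsies: pd.DataFrame) -> dict[str, list[BiopsyRecord]]:
    by_patient: dict[str, list[BiopsyRecord]] = {}
    for _, row in biopsies.iterrows():
        rec = BiopsyRecord(row["patient_id"], row["biopsy_date"],
                           parse_banff(row["banff"]))
        by_patient.setdefault(rec.patient_id, []).append(rec)
    return by_patient


def label_cohort(samples: pd.DataFrame, biopsies: pd.DataFrame,
                 mode: str = "training") -> pd.DataFrame:
    """Label every sample of a cohort table.

    ``mode`` is ``training``, ``test_strict`` or ``test_extended``. Returns
    a DataFrame with one row per sample; no sample is dropped — excluded
    samples carry the label ``excluded``.
    """
    by_patient = _biopsy_records(biopsies)
    rows = []
    for _, sample in samples.iterrows():
        recs = by_patient.get(sample["patient_id"], [])
        if mode == "training":
            ls = label_training(sample, recs)
        elif mode in ("test_strict", "test_extended"):
            ls = label_test(sample, recs, mode.removeprefix("test_"))
        else:
            raise ValueError(f"unknown mode: {mode!r}")
        rows.append(ls.__dict__)
    columns = ["sample_id", "patient_id", "sample_date", "days_post_tx",
               "label", "phase", "basis", "setting"]
    return pd.DataFrame(rows, columns=columns)


def phase_filter(labeled: pd.DataFrame) -> pd.DataFrame:
    """Retain late-phase samples (day >= 15 after transplantation)."""
    if labeled.empty:
        return labeled.copy()
    return labeled[labeled["days_post_tx"] >= LATE_PHASE_MIN_DAY].copy()
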
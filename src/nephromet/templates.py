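"""Metabolite signal templates.

Each template describes one quantified NMR signal: its multiplet geometry
(component offsets relative to the multiplet center and relative weights),
a default line width, a fit window, and optional membership in a joint-fit
group (glucose and glucuronate sit in immediately neighbouring signals and
must be quantified simultaneously to avoid mutual interference).

The shipped chemical shifts are literature-standard values for human urine;
they are versioned project constants, not values taken from any single
study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

#: The ten candidate rejection markers plus creatinine (used for
#: normalization only), in canonical order.
PANEL_METABOLITES = (
    "alanine", "citrate", "dma", "glucose", "glucuronate",
    "hippurate", "lactate", "paq", "trigonelline", "urea", "creatinine",
)

#: The ten candidates eligible for model building (creatinine excluded).
CANDIDATE_METABOLITES = tuple(m for m in PANEL_METABOLITES if m != "creatinine")


@dataclass(frozen=True)
class SignalTemplate:
    """Geometry and fitting constraints for one metabolite signal."""

    metabolite: str
    center: float                       # ppm, multiplet center
    offsets: tuple[float, ...]          # ppm, per-component offset from center
    weights: tuple[float, ...]          # relative component areas, sum to 1
    fwhm: float                         # ppm, default full width at half maximum
    fit_window: tuple[float, float]     # ppm interval used for fitting
    fwhm_bounds: tuple[float, float] = (0.0008, 0.01)
    joint_group: str | None = None      # templates sharing a group are co-fitted
    reference: bool = False             # chemical-shift reference (TSP), not panel

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.weights):
            raise ValueError("offsets and weights must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("component weights must sum to 1")
        lo, hi = self.fit_window
        if not (lo < hi):
            raise ValueError("fit_window must be a non-empty interval")
        for off in self.offsets:
            if not (lo <= self.center + off <= hi):
                raise ValueError(
                    f"{self.metabolite}: component at {self.center + off} "
                    f"outside fit window {self.fit_window}")
        b_lo, b_hi = self.fwhm_bounds
        if not (0 < b_lo < b_hi):
            raise ValueError("fwhm_bounds must be well-ordered and positive")


def _parse(entry: dict) -> SignalTemplate:
    comps = entry["components"]
    return SignalTemplate(
        metabolite=entry["metabolite"],
        center=float(entry["center"]),
        offsets=tuple(float(c["offset"]) for c in comps),
        weights=tuple(float(c["weight"]) for c in comps),
        fwhm=float(entry["fwhm"]),
        fit_window=tuple(entry["fit_window"]),
        fwhm_bounds=tuple(entry.get("fwhm_bounds", (0.0008, 0.01))),
        joint_group=entry.get("joint_group"),
        reference=bool(entry.get("reference", False)),
    )


def load_templates(path=None) -> dict[str, SignalTemplate]:
    """Load signal templates keyed by metabolite name.

    With no argument the versioned templates shipped with the package are
    used; a path to an alternative JSON file may be given instead.
    """
    if path is None:
        text = resources.files("nephromet.data").joinpath(
            "signal_templates.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = json.loads(text)
    templates = {t.metabolite: t for t in map(_parse, doc["templates"])}
    return templates


def panel_templates(templates: dict[str, SignalTemplate] | None = None
                    ) -> dict[str, SignalTemplate]:
    """The 11-signal quantification panel (reference signals removed)."""
    templates = templates or load_templates()
    return {k: v for k, v in templates.items() if not v.reference}
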
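"""Iterative random-forest feature selection over spectral bins.

Repeated cross-validated random forests score every bin by held-out
permutation importance; scores are aggregated by the median and bins at or
below an importance threshold are eliminated, iterating until the selected
set is stable. Bin-quality flags (a quantitative stand-in for visual
assessment of candidate bins) remove bins dominated by noise or baseline,
or bins whose peak straddles a bin boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold

from nephromet.preprocess import BinFeatureTable
from nephromet.spectrum import Spectrum


@dataclass(frozen=True)
class SelectionConfig:
    n_repeats: int = 20          # repeated CV rounds
    n_folds: int = 5
    n_trees: int = 200
    perm_repeats: int = 5        # permutation-importance shuffles per fold
    importance_threshold: float = 0.0   # eliminate bins at or below this
    max_iterations: int = 3


@dataclass
class SelectionResult:
    """Ranked bins with the selected/eliminated partition."""

    ranked_bins: pd.Series          # importance by bin id, descending
    selected: list
    eliminated: dict                # bin id -> reason code
    iterations: int
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.selected) & set(self.eliminated)
        if overlap:
            raise ValueError(f"bins both selected and eliminated: {overlap}")


def _median_importance(X: np.ndarray, y: np.ndarray, cfg: SelectionConfig,
                       rng: np.random.Generator) -> np.ndarray:
    """Median held-out permutation importance over repeats x folds."""
    scores = []
    for _ in range(cfg.n_repeats):
        skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                              random_state=int(rng.integers(2**31)))
        for train, test in skf.split(X, y):
            rf = RandomForestClassifier(
                n_estimators=cfg.n_trees,
                random_state=int(rng.integers(2**31)), n_jobs=1)
            rf.fit(X[train], y[train])
            imp = permutation_importance(
                rf, X[test], y[test], n_repeats=cfg.perm_repeats,
                random_state=int(rng.integers(2**31)), n_jobs=1)
            scores.append(imp.importances_mean)
    return np.median(np.vstack(scores), axis=0)


def rf_feature_selection(features, labels,
                         config: SelectionConfig | None = None,
                         seed: int = 0,
                         quality_flags: dict | None = None
                         ) -> SelectionResult:
    """Select informative bins by iterated RF permutation importance.

    ``features`` is a DataFrame (columns = bin ids) or a
    :class:`BinFeatureTable` at the autoscaled stage. Bins named in
    ``quality_flags`` (bin id -> reason) are eliminated up front. Each
    iteration re-scores the surviving bins and drops those whose median
    importance is at or below ``importance_threshold``; iteration stops
    when the set is stable or ``max_iterations`` is reached.
    """
    cfg = config or SelectionConfig()
    if isinstance(features, BinFeatureTable):
        cols = [f"bin_{i}" for i in range(features.n_bins)]
        features = pd.DataFrame(features.values, columns=cols)
    X_all = features.to_numpy(dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain at least two classes")
    if not np.all(np.isfinite(X_all)):
        raise ValueError("features must be finite (drop invalid samples first)")

    rng = np.random.default_rng(seed)
    eliminated: dict = dict(quality_flags or {})
    active = [c for c in features.columns if c not in eliminated]

    last_importance = pd.Series(dtype=float)
    iterations = 0
    for iterations in range(1, cfg.max_iterations + 1):
        idx = [features.columns.get_loc(c) for c in active]
        imp = _median_importance(X_all[:, idx], y, cfg, rng)
        last_importance = pd.Series(imp, index=active)
        drop = last_importance[last_importance <= cfg.importance_threshold]
        if drop.empty:
            break
        for c in drop.index:
            eliminated[c] = "low_importance"
        active = [c for c in active if c not in eliminated]
        if not active:
            break

    ranked = last_importance.sort_values(ascending=False)
    return SelectionResult(ranked_bins=ranked, selected=list(active),
                           eliminated=eliminated, iterations=iterations,
                           seed=seed)


def assess_bin_quality(spectra: list[Spectrum], table: BinFeatureTable,
                       noise_region: tuple[float, float] = (9.55, 9.95),
                       min_snr: float = 5.0,
                       edge_fraction: float = 0.1,
                       max_baseline_fraction: float = 0.6) -> dict:
    """Flag bins unsuitable as features; quantitative stand-in for visual review.

    On the mean spectrum each bin is checked for (a) a peak rising at least
    ``min_snr`` noise levels above the bin's local floor (otherwise
    ``low_signal``), (b) a dominant apex within ``edge_fraction`` of a bin
    edge (``edge_peak`` — a peak straddling the boundary splits its area
    across bins), and (c) a local floor carrying most of the bin's integral
    (``baseline``). Returns {bin_id: reason} for flagged bins only.
    """
    mean_y = np.mean([sp.intensities for sp in spectra], axis=0)
    ref = spectra[0]
    ppm = ref.ppm
    m = (ppm >= noise_region[0]) & (ppm <= noise_region[1])
    noise = 1.4826 * np.median(np.abs(mean_y[m] - np.median(mean_y[m])))
    noise = max(noise, 1e-12)

    flags: dict = {}
    for k, (lo, hi) in enumerate(table.bin_edges):
        sel = (ppm >= lo) & (ppm <= hi)
        if not sel.any():
            flags[f"bin_{k}"] = "empty"
            continue
        y = mean_y[sel]
        x = ppm[sel]
        floor = np.median(y)
        height = float(y.max() - floor)
        if height < min_snr * noise:
            flags[f"bin_{k}"] = "low_signal"
            continue
        apex = x[np.argmax(y)]
        width = hi - lo
        if apex - lo < edge_fraction * width or hi - apex < edge_fraction * width:
            flags[f"bin_{k}"] = "edge_peak"
            continue
        total = float(np.trapezoid(y, x))
        if total > 0 and (floor * width) / total > max_baseline_fraction:
            flags[f"bin_{k}"] = "baseline"
    return flags
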
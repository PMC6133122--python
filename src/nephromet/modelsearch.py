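"""Exhaustive logistic model search over metabolite subsets.

All subsets of up to five of the ten candidate metabolites (637 models)
are fitted as unpenalized logistic regressions and judged by
patient-grouped, repeated cross-validated AUC on the training cohort and
by plain AUC on the held-out test settings. A random-forest learner can be
run through the identical folds as a parsimony check.

The modelling surface follows the Model/Results idiom:
``PanelLogisticModel(X, y).fit()`` returns a
:class:`PanelLogisticResults`; ``ExhaustiveSearch(X, y, groups).fit()``
returns a :class:`SearchResults` carrying one :class:`ModelCandidate` per
subset and a leaderboard.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve


def enumerate_subsets(n_features: int, max_size: int) -> list[tuple[int, ...]]:
    """All index subsets of size 1..max_size, each once, deterministic order.

    With 10 features and max size 5 this enumerates the 637 candidate
    models of the exhaustive search.
    """
    if not (1 <= max_size <= n_features):
        raise ValueError("require 1 <= max_size <= n_features")
    out: list[tuple[int, ...]] = []
    for size in range(1, max_size + 1):
        out.extend(itertools.combinations(range(n_features), size))
    return out


# --------------------------------------------------------------------------
# single-model fitting

class PanelLogisticModel:
    """Unpenalized logistic regression on a metabolite feature panel.

    Parameters
    ----------
    X : DataFrame or array
        Feature matrix (standardized metabolite intensities).
    y : array-like
        Binary labels (1 = case).
    feature_names : optional
        Names for array input; DataFrames supply their own columns.
    """

    def __init__(self, X, y, feature_names=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names = (list(feature_names) if feature_names
                                  else [f"x{i}" for i in range(X.shape[1])])
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X and y have incompatible shapes")
        if len(np.unique(y)) < 2:
            raise ValueError("labels must contain both classes")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite (complete-case rows only)")
        self.X, self.y = X, y

    def fit(self, maxiter: int = 200) -> "PanelLogisticResults":
        Xc = sm.add_constant(self.X, has_constant="add")
        separable = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(self.y, Xc).fit(disp=0, maxiter=maxiter)
                params, bse = res.params, res.bse
                converged = bool(res.mle_retvals.get("converged", True))
                llf = float(res.llf)
            except Exception:
                # perfect separation (or similar degeneracy): flag, return
                # a penalized surrogate so downstream code stays total
                separable = True
                clf = LogisticRegression(C=1e6, max_iter=1000).fit(self.X,
                                                                   self.y)
                params = np.concatenate([clf.intercept_, clf.coef_[0]])
                bse = np.full(params.size, np.nan)
                converged, llf = False, float("nan")
        if not separable and np.max(np.abs(params)) > 50:
            separable = True
        return PanelLogisticResults(
            params=pd.Series(params, index=["const"] + self.feature_names),
            bse=pd.Series(np.asarray(bse), index=["const"] + self.feature_names),
            llf=llf, converged=converged, separable=separable,
            nobs=self.y.size, model=self)


@dataclass
class PanelLogisticResults:
    """Fitted coefficients, standard errors and diagnostics."""

    params: pd.Series
    bse: pd.Series
    llf: float
    converged: bool
    separable: bool
    nobs: int
    model: PanelLogisticModel

    def predict(self, X) -> np.ndarray:
        """Predicted case probabilities."""
        if isinstance(X, pd.DataFrame):
            X = X[self.model.feature_names].to_numpy(dtype=float)
        eta = self.params.iloc[0] + np.asarray(X, float) @ self.params.iloc[1:].to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))

    def summary(self) -> pd.DataFrame:
        tab = pd.DataFrame({"coef": self.params, "std_err": self.bse})
        tab["z"] = tab["coef"] / tab["std_err"]
        return tab

    def __str__(self) -> str:
        flags = []
        if not self.converged:
            flags.append("NOT CONVERGED")
        if self.separable:
            flags.append("SEPARABLE")
        head = (f"Logistic panel model  n={self.nobs}  llf={self.llf:.3f}"
                + ("  [" + ", ".join(flags) + "]" if flags else ""))
        return head + "\n" + self.summary().to_string(float_format="%.6f")


def fit_logistic(X, y, feature_names=None) -> PanelLogisticResults:
    """Convenience wrapper: fit one unpenalized logistic model."""
    return PanelLogisticModel(X, y, feature_names=feature_names).fit()


# --------------------------------------------------------------------------
# cross-validation

def _grouped_folds(groups: np.ndarray, y: np.ndarray, folds: int,
                   rng: np.random.Generator, max_redraw: int = 20
                   ) -> list[np.ndarray]:
    """Shuffle patients into folds; every training split must see both classes."""
    uniq = np.unique(groups)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    for _ in range(max_redraw):
        perm = rng.permutation(uniq)
        assignment = {g: i % folds for i, g in enumerate(perm)}
        fold_of = np.array([assignment[g] for g in groups])
        ok = all(len(np.unique(y[fold_of != f])) == 2
                 and (fold_of == f).any() for f in range(folds))
        if ok:
            return [np.where(fold_of == f)[0] for f in range(folds)]
    raise ValueError("could not build folds with both classes in every "
                     "training split")


def _cv_pooled_auc(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                   folds: int, repeats: int, rng: np.random.Generator,
                   make_estimator) -> float:
    """Mean over repeats of the AUC of pooled held-out predictions."""
    aucs = []
    for _ in range(repeats):
        test_folds = _grouped_folds(groups, y, folds, rng)
        preds = np.empty_like(y, dtype=float)
        for test_idx in test_folds:
            train_mask = np.ones(y.size, bool)
            train_mask[test_idx] = False
            est = make_estimator(int(rng.integers(2**31)))
            est.fit(X[train_mask], y[train_mask])
            preds[test_idx] = est.predict_proba(X[test_idx])[:, 1]
        aucs.append(roc_auc_score(y, preds))
    return float(np.mean(aucs))


def cv_auc(X, y, groups=None, folds: int = 5, repeats: int = 10,
           seed: int = 0) -> float:
    """Patient-grouped repeated k-fold cross-validated AUC.

    Grouping keeps every patient's repeated samples inside one fold,
    preventing leakage between training and held-out data. Held-out
    predicted probabilities are pooled within each repeat, the AUC
    computed, and the mean over repeats returned. Deterministic for a
    given seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    groups = np.arange(y.size) if groups is None else np.asarray(groups)
    rng = np.random.default_rng(seed)
    return _cv_pooled_auc(
        X, y, groups, folds, repeats, rng,
        lambda s: LogisticRegression(C=np.inf, max_iter=1000))


def compare_rf_vs_logistic(X, y, groups=None, folds: int = 5,
                           repeats: int = 3, seed: int = 0,
                           n_trees: int = 200) -> dict[str, float]:
    """Cross-validated AUC of logistic regression vs a random forest.

    Both learners see exactly the same folds, so the comparison isolates
    the learner (parsimony check: when the true log-odds are linear the
    simpler logistic model should not be outperformed).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    groups = np.arange(y.size) if groups is None else np.asarray(groups)
    rng = np.random.default_rng(seed)

    auc_lr, auc_rf = [], []
    for _ in range(repeats):
        test_folds = _grouped_folds(groups, y, folds, rng)
        preds_lr = np.empty_like(y, dtype=float)
        preds_rf = np.empty_like(y, dtype=float)
        for test_idx in test_folds:
            train_mask = np.ones(y.size, bool)
            train_mask[test_idx] = False
            lr = LogisticRegression(C=np.inf, max_iter=1000)
            rf = RandomForestClassifier(n_estimators=n_trees,
                                        random_state=int(rng.integers(2**31)),
                                        n_jobs=1)
            lr.fit(X[train_mask], y[train_mask])
            rf.fit(X[train_mask], y[train_mask])
            preds_lr[test_idx] = lr.predict_proba(X[test_idx])[:, 1]
            preds_rf[test_idx] = rf.predict_proba(X[test_idx])[:, 1]
        auc_lr.append(roc_auc_score(y, preds_lr))
        auc_rf.append(roc_auc_score(y, preds_rf))
    return {"logistic": float(np.mean(auc_lr)), "rf": float(np.mean(auc_rf))}


# --------------------------------------------------------------------------
# ROC

@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-9 <= self.auc <= self.ci_high + 1e-9):
            raise ValueError("AUC outside its confidence interval")


def roc_auc(scores, labels, n_boot: int = 2000, seed: int = 0) -> ROCResult:
    """ROC curve with AUC and a stratified-bootstrap 95% CI.

    The AUC is the rank/trapezoid value, identical to the Mann-Whitney
    U-statistic with half credit for ties. Cases and controls are
    resampled separately for the bootstrap.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels must contain both classes")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc_val = float(roc_auc_score(labels, scores))

    rng = np.random.default_rng(seed)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        cs = rng.choice(cases, size=cases.size, replace=True)
        ct = rng.choice(controls, size=controls.size, replace=True)
        bs = np.concatenate([cs, ct])
        bl = np.concatenate([np.ones(cs.size, int), np.zeros(ct.size, int)])
        boots[b] = roc_auc_score(bl, bs)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ROCResult(thresholds=thr, sensitivities=tpr,
                     specificities=1.0 - fpr, auc=auc_val,
                     ci_low=float(min(lo, auc_val)),
                     ci_high=float(max(hi, auc_val)))


# --------------------------------------------------------------------------
# exhaustive search

@dataclass
class ModelCandidate:
    """One feature subset with its fitted coefficients and AUC record."""

    features: tuple[str, ...]
    coefficients: dict[str, float]      # includes 'const'
    cv_auc_train: float
    auc_test: dict[str, float] = field(default_factory=dict)
    n_used: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (1 <= len(self.features)):
            raise ValueError("a candidate needs at least one feature")

    @property
    def feature_set(self) -> frozenset:
        return frozenset(self.features)

    def auc(self, setting: str) -> float:
        """AUC under 'train' or a named test setting."""
        if setting == "train":
            return self.cv_auc_train
        return self.auc_test.get(setting, float("nan"))


@dataclass
class SearchResults:
    candidates: list[ModelCandidate]
    max_size: int
    seed: int

    def leaderboard(self) -> pd.DataFrame:
        rows = []
        for c in self.candidates:
            row = {"features": "+".join(c.features),
                   "size": len(c.features),
                   "cv_auc_train": c.cv_auc_train,
                   "n_used": c.n_used,
                   "flags": ";".join(c.flags)}
            for k, v in c.auc_test.items():
                row[f"auc_{k}"] = v
            rows.append(row)
        df = pd.DataFrame(rows)
        return df.sort_values("cv_auc_train", ascending=False,
                              ignore_index=True)

    def summary(self, top: int = 10) -> str:
        lb = self.leaderboard().head(top)
        return (f"Exhaustive search: {len(self.candidates)} candidates "
                f"(subsets up to size {self.max_size})\n"
                + lb.to_string(float_format="%.4f"))


class ExhaustiveSearch:
    """Enumerate and evaluate all metabolite subsets up to ``max_size``.

    Parameters
    ----------
    features : DataFrame
        Training feature table (columns = metabolites); NaN marks an
        invalid quantification — each candidate uses its complete cases.
    labels : array-like of {0, 1}
    groups : array-like, optional
        Patient ids for grouped cross-validation.
    """

    def __init__(self, features: pd.DataFrame, labels, groups=None):
        self.features = features
        self.labels = np.asarray(labels, dtype=int)
        self.groups = (np.asarray(groups) if groups is not None
                       else np.arange(len(features)))

    def fit(self, max_size: int = 5, folds: int = 5, repeats: int = 10,
            seed: int = 0, test_sets: dict | None = None,
            min_n: int = 20) -> SearchResults:
        """Evaluate every subset; ``test_sets`` maps setting name to
        (features DataFrame, labels)."""
        cols = list(self.features.columns)
        subsets = enumerate_subsets(len(cols), max_size)
        rng = np.random.default_rng(seed)
        candidates = []
        for subset in subsets:
            names = tuple(cols[i] for i in subset)
            sub = self.features[list(names)]
            mask = sub.notna().all(axis=1).to_numpy()
            X = sub.to_numpy(dtype=float)[mask]
            y = self.labels[mask]
            g = self.groups[mask]
            flags = []
            cand_seed = int(rng.integers(2**31))
            if mask.sum() < min_n or len(np.unique(y)) < 2:
                candidates.append(ModelCandidate(
                    features=names, coefficients={},
                    cv_auc_train=float("nan"), n_used=int(mask.sum()),
                    flags=["insufficient_data"]))
                continue
            try:
                auc_train = cv_auc(X, y, groups=g, folds=folds,
                                   repeats=repeats, seed=cand_seed)
            except ValueError:
                auc_train = float("nan")
                flags.append("cv_failed")
            res = fit_logistic(X, y, feature_names=list(names))
            if res.separable:
                flags.append("separable")
            if not res.converged:
                flags.append("not_converged")
            auc_test = {}
            if test_sets:
                for setting, (tf, tl) in test_sets.items():
                    tsub = tf[list(names)]
                    tmask = tsub.notna().all(axis=1).to_numpy()
                    tl_arr = np.asarray(tl, dtype=int)[tmask]
                    if tmask.sum() == 0 or len(np.unique(tl_arr)) < 2:
                        auc_test[setting] = float("nan")
                        continue
                    probs = res.predict(tsub[tmask])
                    auc_test[setting] = float(roc_auc_score(tl_arr, probs))
            candidates.append(ModelCandidate(
                features=names,
                coefficients=res.params.to_dict(),
                cv_auc_train=auc_train, auc_test=auc_test,
                n_used=int(mask.sum()), flags=flags))
        return SearchResults(candidates=candidates, max_size=max_size,
                             seed=seed)
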
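"""Gradient-boosted-tree modelling: hyperparameter tuning (TPE),
group-aware cross-validated evaluation, ROC/AUROC, Youden-threshold
metrics and partial-dependence curves.

AUROC is the probability that a random positive outscores a random
negative, ties counted half (the pairwise / Mann-Whitney definition).
Youden's index J = TPR + TNR − 1 is maximized over all distinct score
thresholds to pick an operating point; ties go to the lowest qualifying
threshold (the more sensitive operating point).

Hyperparameters are searched with a Tree-structured Parzen Estimator:
after a random start-up phase, observed trials are split into a "good"
quantile and the rest, one density per dimension is fitted to each side
(Gaussian KDE for continuous/integer dimensions, smoothed category
frequencies for choices), candidates are drawn from the good density and
the one maximizing the density ratio l(x)/g(x) is evaluated next. The
sampler is authored here and fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedGroupKFold
from xgboost import XGBClassifier

from .errors import ConfigurationError, InputError, MetricError

__all__ = [
    "Uniform", "LogUniform", "IntUniform", "Choice",
    "ModelParams", "ModelEvaluation", "ThresholdMetrics", "PDPCurve",
    "DEFAULT_SEARCH_SPACE", "DEFAULT_XGB_PARAMS",
    "auroc", "make_classifier", "tune_hyperparameters",
    "crossval_evaluate", "youden_metrics", "partial_dependence",
]

FPR_GRID = np.linspace(0.0, 1.0, 101)

DEFAULT_XGB_PARAMS: dict = {
    "n_estimators": 100,
    "max_depth": 4,
    "learning_rate": 0.1,
    "subsample": 0.9,
    "colsample_bytree": 0.9,
    "min_child_weight": 1.0,
    "reg_lambda": 1.0,
    "scale_pos_weight": 1.0,
}

# compact defaults for test-scale runs
SMOKE_XGB_PARAMS: dict = {**DEFAULT_XGB_PARAMS, "n_estimators": 25, "max_depth": 3}


# ---------------------------------------------------------------------------
# search-space primitives

@dataclass(frozen=True)
class Uniform:
    low: float
    high: float
    default: float | None = None


@dataclass(frozen=True)
class LogUniform:
    low: float
    high: float
    default: float | None = None


@dataclass(frozen=True)
class IntUniform:
    low: int
    high: int
    default: int | None = None


@dataclass(frozen=True)
class Choice:
    options: tuple
    default: object | None = None


DEFAULT_SEARCH_SPACE: dict = {
    "n_estimators": IntUniform(50, 400, default=100),
    "max_depth": IntUniform(2, 8, default=4),
    "learning_rate": LogUniform(0.01, 0.3, default=0.1),
    "subsample": Uniform(0.5, 1.0, default=0.9),
    "colsample_bytree": Uniform(0.5, 1.0, default=0.9),
    "min_child_weight": LogUniform(0.5, 10.0, default=1.0),
    "reg_lambda": LogUniform(0.1, 10.0, default=1.0),
    "scale_pos_weight": LogUniform(1.0, 30.0, default=1.0),
}


@dataclass
class ModelParams:
    params: dict
    score: float | None = None
    space: dict | None = None
    tuning_seed: int | None = None


@dataclass
class ModelEvaluation:
    fold_auroc: np.ndarray
    mean_auroc: float
    ci: tuple
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    tpr_ci_low: np.ndarray
    tpr_ci_high: np.ndarray
    fold_threshold_metrics: list = field(default_factory=list)

    def threshold_summary(self) -> pd.DataFrame:
        """Table-style mean ± sd of the per-fold Youden-threshold metrics."""
        rows = [dict(TPR=m.tpr, TNR=m.tnr, PPV=m.ppv, F1=m.f1, J=m.j)
                for m in self.fold_threshold_metrics]
        df = pd.DataFrame(rows)
        return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})


@dataclass
class ThresholdMetrics:
    threshold: float
    tpr: float
    tnr: float
    ppv: float
    f1: float
    j: float


@dataclass
class PDPCurve:
    feature: str
    grid: np.ndarray
    response: np.ndarray
    group_curves: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# metrics

def auroc(scores, labels) -> float:
    """Pairwise AUROC via midranks: P(score⁺ > score⁻) + ½P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUROC needs both classes present")
    ranks = stats.rankdata(s)  # midranks handle ties at half credit
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def youden_metrics(scores, labels) -> ThresholdMetrics:
    """Metrics at the threshold maximizing J = TPR + TNR − 1.

    Scans all distinct score values as thresholds (predict positive iff
    score >= threshold); ties in J resolve to the lowest threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise MetricError("threshold metrics need both classes present")
    best = None
    for thr in np.sort(np.unique(s)):
        pred = s >= thr
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        tpr = tp / n_pos
        tnr = (n_neg - fp) / n_neg
        j = tpr + tnr - 1.0
        if best is None or j > best[0] + 1e-12:
            ppv = tp / (tp + fp) if (tp + fp) else 0.0
            f1 = (2 * tpr * ppv / (tpr + ppv)) if (tpr + ppv) else 0.0
            best = (j, ThresholdMetrics(float(thr), tpr, tnr, ppv, f1, j))
    return best[1]


# ---------------------------------------------------------------------------
# classifier construction

def make_classifier(params: dict, seed: int = 0) -> XGBClassifier:
    merged = {**DEFAULT_XGB_PARAMS, **params}
    merged["n_estimators"] = int(merged["n_estimators"])
    merged["max_depth"] = int(merged["max_depth"])
    return XGBClassifier(
        **merged,
        objective="binary:logistic",
        eval_metric="logloss",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        verbosity=0,
    )


# ---------------------------------------------------------------------------
# TPE sampler

class _TPESampler:
    """Minimal Tree-structured Parzen Estimator over a dict search space."""

    def __init__(self, space: dict, seed: int, n_startup: int = 10,
                 gamma: float = 0.25, n_candidates: int = 24):
        self.space = space
        self.rng = np.random.default_rng(seed)
        self.n_startup = n_startup
        self.gamma = gamma
        self.n_candidates = n_candidates
        self.trials: list[tuple[dict, float]] = []

    def _sample_random(self) -> dict:
        out = {}
        for name, dim in self.space.items():
            if isinstance(dim, Uniform):
                out[name] = float(self.rng.uniform(dim.low, dim.high))
            elif isinstance(dim, LogUniform):
                out[name] = float(np.exp(self.rng.uniform(
                    np.log(dim.low), np.log(dim.high))))
            elif isinstance(dim, IntUniform):
                out[name] = int(self.rng.integers(dim.low, dim.high + 1))
            elif isinstance(dim, Choice):
                out[name] = dim.options[self.rng.integers(len(dim.options))]
            else:
                raise ConfigurationError(f"unknown dimension type for {name!r}")
        return out

    def _kde(self, values: np.ndarray, dim) -> stats.gaussian_kde:
        if isinstance(dim, LogUniform):
            values = np.log(values)
        jitter = self.rng.normal(0, 1e-6, size=values.size)
        data = values.astype(float) + jitter
        if data.size < 2 or np.std(data) == 0:
            data = np.concatenate([data, data + 1e-3])
        return stats.gaussian_kde(data)

    def suggest(self) -> dict:
        if len(self.trials) < self.n_startup:
            return self._sample_random()
        scores = np.array([s for _, s in self.trials])
        n_good = max(1, int(np.ceil(self.gamma * len(self.trials))))
        good_idx = np.argsort(-scores, kind="stable")[:n_good]
        good = [self.trials[i][0] for i in good_idx]
        bad = [self.trials[i][0] for i in range(len(self.trials))
               if i not in set(good_idx.tolist())]
        if not bad:
            return self._sample_random()

        best_cand, best_ratio = None, -np.inf
        for _ in range(self.n_candidates):
            cand = {}
            log_ratio = 0.0
            for name, dim in self.space.items():
                gv = np.array([t[name] for t in good], dtype=float) \
                    if not isinstance(dim, Choice) else [t[name] for t in good]
                bv = np.array([t[name] for t in bad], dtype=float) \
                    if not isinstance(dim, Choice) else [t[name] for t in bad]
                if isinstance(dim, Choice):
                    opts = list(dim.options)
                    counts = np.array([gv.count(o) + 1.0 for o in opts])
                    probs = counts / counts.sum()
                    pick = opts[self.rng.choice(len(opts), p=probs)]
                    bcounts = np.array([bv.count(o) + 1.0 for o in opts])
                    bprobs = bcounts / bcounts.sum()
                    cand[name] = pick
                    log_ratio += np.log(probs[opts.index(pick)]) - \
                        np.log(bprobs[opts.index(pick)])
                    continue
                kde_g = self._kde(gv, dim)
                kde_b = self._kde(bv, dim)
                draw = float(kde_g.resample(1, seed=self.rng)[0, 0])
                if isinstance(dim, LogUniform):
                    draw = float(np.clip(draw, np.log(dim.low), np.log(dim.high)))
                    value = float(np.exp(draw))
                    point = draw
                elif isinstance(dim, IntUniform):
                    value = int(np.clip(round(draw), dim.low, dim.high))
                    point = float(value)
                else:
                    value = float(np.clip(draw, dim.low, dim.high))
                    point = value
                cand[name] = value
                lg = max(float(kde_g(point)[0]), 1e-12)
                lb = max(float(kde_b(point)[0]), 1e-12)
                log_ratio += np.log(lg) - np.log(lb)
            if log_ratio > best_ratio:
                best_ratio, best_cand = log_ratio, cand
        return best_cand

    def tell(self, params: dict, score: float) -> None:
        self.trials.append((params, float(score)))


def _space_default(space: dict) -> dict | None:
    """The space's declared default point, if every dimension has one."""
    out = {}
    for name, dim in space.items():
        if dim.default is None:
            return None
        out[name] = dim.default
    return out


def _grouped_stratified_folds(y: np.ndarray, groups: np.ndarray, k: int,
                              seed: int):
    """Group-disjoint, approximately stratified folds; refolds with a new
    seed if some fold ends up single-class (logged by the caller)."""
    for attempt in range(20):
        splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                        random_state=seed + attempt)
        folds = list(splitter.split(np.zeros(len(y)), y, groups))
        if all(len(np.unique(y[test])) == 2 for _, test in folds):
            return folds, attempt
    return folds, attempt  # caller decides how to handle residual degeneracy


def _cv_auroc(X: pd.DataFrame, y: np.ndarray, groups: np.ndarray,
              params: dict, k: int, seed: int) -> float:
    folds, _ = _grouped_stratified_folds(y, groups, k, seed)
    scores = []
    for train_idx, test_idx in folds:
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
            continue
        clf = make_classifier(params, seed=seed)
        clf.fit(X.iloc[train_idx], y[train_idx])
        p = clf.predict_proba(X.iloc[test_idx])[:, 1]
        scores.append(auroc(p, y[test_idx]))
    if not scores:
        raise MetricError("every fold was single-class")
    return float(np.mean(scores))


def tune_hyperparameters(X: pd.DataFrame, y, groups=None,
                         space: dict | None = None, n_folds: int = 20,
                         n_trials: int = 100, seed: int = 0) -> ModelParams:
    """TPE search maximizing mean cross-validated AUROC.

    Trial 0 evaluates the space's declared default point when available, so
    the returned configuration never scores below the default on the same
    folds. Deterministic given the seed.
    """
    space = space if space is not None else DEFAULT_SEARCH_SPACE
    if not space:
        raise ConfigurationError("empty search space")
    y = np.asarray(y).astype(int)
    groups = (np.asarray(groups) if groups is not None
              else np.arange(len(y)))
    n_folds = min(n_folds, max(2, int(min((y == 1).sum(), (y == 0).sum()))))
    sampler = _TPESampler(space, seed=seed)
    best: tuple[float, dict] | None = None
    default_point = _space_default(space)
    for trial in range(n_trials):
        if trial == 0 and default_point is not None:
            params = dict(default_point)
        else:
            params = sampler.suggest()
        score = _cv_auroc(X, y, groups, params, n_folds, seed)
        sampler.tell(params, score)
        if best is None or score > best[0]:
            best = (score, params)
    return ModelParams(params=best[1], score=best[0], space=space,
                       tuning_seed=seed)


def crossval_evaluate(X: pd.DataFrame, y, groups=None, params: dict | None = None,
                      k: int = 10, seed: int = 0) -> ModelEvaluation:
    """k-fold group-disjoint evaluation: per-fold AUROC and
    Youden-threshold metrics, mean AUROC with Student-t 95% CI, and a
    vertically averaged ROC curve on a fixed 101-point FPR grid."""
    y = np.asarray(y).astype(int)
    groups = np.asarray(groups) if groups is not None else np.arange(len(y))
    params = params or DEFAULT_XGB_PARAMS
    folds, _ = _grouped_stratified_folds(y, groups, k, seed)

    fold_scores, tprs, thr_metrics = [], [], []
    for train_idx, test_idx in folds:
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
            continue
        clf = make_classifier(params, seed=seed)
        clf.fit(X.iloc[train_idx], y[train_idx])
        p = clf.predict_proba(X.iloc[test_idx])[:, 1]
        fold_scores.append(auroc(p, y[test_idx]))
        fpr, tpr, _ = roc_curve(y[test_idx], p)
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
        thr_metrics.append(youden_metrics(p, y[test_idx]))
    if not fold_scores:
        raise MetricError("no usable folds")

    arr = np.array(fold_scores)
    mean = float(arr.mean())
    if len(arr) > 1 and arr.std(ddof=1) > 0:
        half = stats.t.ppf(0.975, len(arr) - 1) * arr.std(ddof=1) / np.sqrt(len(arr))
    else:
        half = 0.0
    tpr_mat = np.vstack(tprs)
    tpr_mean = tpr_mat.mean(axis=0)
    if tpr_mat.shape[0] > 1:
        tpr_half = stats.t.ppf(0.975, tpr_mat.shape[0] - 1) * \
            tpr_mat.std(axis=0, ddof=1) / np.sqrt(tpr_mat.shape[0])
    else:
        tpr_half = np.zeros_like(tpr_mean)
    return ModelEvaluation(
        fold_auroc=arr, mean_auroc=mean, ci=(mean - half, mean + half),
        fpr_grid=FPR_GRID, mean_tpr=tpr_mean,
        tpr_ci_low=np.clip(tpr_mean - tpr_half, 0, 1),
        tpr_ci_high=np.clip(tpr_mean + tpr_half, 0, 1),
        fold_threshold_metrics=thr_metrics)


def partial_dependence(model, table: pd.DataFrame, feature: str,
                       grid=None, group_labels=None) -> PDPCurve:
    """Average predicted positive probability as one feature is swept over
    a grid (default: 50 points between the 5th and 95th percentiles) while
    all other features keep their observed values. ``group_labels``
    optionally adds per-group curves (e.g. by diagnosed T2D status)."""
    if feature not in table.columns:
        raise InputError(f"unknown feature {feature!r}")
    if grid is None:
        lo, hi = np.nanpercentile(table[feature].to_numpy(dtype=float), [5, 95])
        if lo == hi:
            hi = lo + 1e-9
        grid = np.linspace(lo, hi, 50)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise InputError("grid must be strictly increasing")

    def _predict(tbl: pd.DataFrame) -> np.ndarray:
        if hasattr(model, "predict_proba"):
            return model.predict_proba(tbl)[:, 1]
        return np.asarray(model.predict(tbl), dtype=float)

    def _curve(rows: pd.DataFrame) -> np.ndarray:
        out = np.empty(grid.size)
        work = rows.copy()
        for i, v in enumerate(grid):
            work[feature] = v
            out[i] = float(_predict(work).mean())
        return out

    response = _curve(table)
    group_curves = {}
    if group_labels is not None:
        gl = pd.Series(np.asarray(group_labels), index=table.index)
        for g in gl.unique():
            group_curves[g] = _curve(table.loc[gl == g])
    return PDPCurve(feature=feature, grid=grid, response=response,
                    group_curves=group_curves)
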
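"""Two-phase feature selection.

Phase 1 — permutation importance (PI): over repeated region-grouped 70/30
splits a gradient-boosted-tree classifier is fitted on the training side
and scored on the test side; each feature's test-set column is then
shuffled and the AUROC drop recorded. The 95% Student-t confidence
interval of each feature's mean drop gates significance: a feature
contributes significantly iff its CI lies strictly in the positive reals.
A Spearman rank correlation with the target annotates the direction of
each feature's marginal association.

Phase 2 — backward sequential feature selection (SFS): starting from the
significant set, each step removes the feature whose removal yields the
best mean validation AUROC over a fixed battery of seeded splits (shared
across candidates within a step, so comparisons are paired), down to one
feature; the selected subset is the step — including step 0 — with the
highest mean score.

Splits always keep whole region groups on one side, preventing geospatial
leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MetricError, SelectionError, SplitError
from .modeling import auroc, make_classifier

__all__ = [
    "PIResults",
    "SFSTrace",
    "grouped_split",
    "permutation_importance",
    "significant_features",
    "spearman_sign",
    "backward_sfs",
]


@dataclass
class PIResults:
    """Per-feature permutation-importance distributions with CI gate."""

    drops: pd.DataFrame            # repetitions x features
    mean_drop: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    significant: pd.Series         # CI strictly within the positive reals
    spearman_r: pd.Series
    spearman_p: pd.Series
    base_scores: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "mean_drop": self.mean_drop, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "significant": self.significant,
            "spearman_r": self.spearman_r, "spearman_p": self.spearman_p,
        })

    def plot_data(self) -> pd.DataFrame:
        """Box-plot quantiles plus CI per feature, for ranked-importance
        plots."""
        q = self.drops.quantile([0.0, 0.25, 0.5, 0.75, 1.0]).T
        q.columns = ["min", "q1", "median", "q3", "max"]
        q["mean"] = self.mean_drop
        q["ci_low"] = self.ci_low
        q["ci_high"] = self.ci_high
        return q.sort_values("mean", ascending=False)


@dataclass
class SFSTrace:
    """Ordered removal trace with per-step mean scores."""

    start_features: list
    start_score: float
    removals: list            # [(feature removed, mean score after removal)]
    selected: list
    selected_score: float

    def step_scores(self) -> list:
        return [self.start_score] + [s for _, s in self.removals]


def grouped_split(groups, test_fraction: float, seed: int):
    """Assign whole groups to train or test, greedily matching the target
    test fraction as closely as possible. Returns (train_idx, test_idx)."""
    g = pd.Series(np.asarray(groups))
    unique = g.unique()
    if len(unique) < 2:
        raise SplitError("grouped split needs at least two groups")
    rng = np.random.default_rng(seed)
    order = rng.permutation(unique)
    sizes = g.value_counts()
    target = test_fraction * len(g)
    test_groups, current = [], 0
    for grp in order:
        size = sizes[grp]
        if abs(current + size - target) <= abs(current - target):
            test_groups.append(grp)
            current += size
    if not test_groups:          # degenerate tiny-fraction case
        test_groups = [order[0]]
    if len(test_groups) == len(unique):
        test_groups = test_groups[:-1]
    test_mask = g.isin(test_groups).to_numpy()
    idx = np.arange(len(g))
    return idx[~test_mask], idx[test_mask]


def _t_ci(values: np.ndarray, level: float = 0.95):
    m = values.mean()
    if values.size < 2 or values.std(ddof=1) == 0:
        return m, m
    half = stats.t.ppf(0.5 + level / 2, values.size - 1) * \
        values.std(ddof=1) / np.sqrt(values.size)
    return m - half, m + half


def permutation_importance(X: pd.DataFrame, y, groups=None,
                           model_params: dict | None = None,
                           n_reps: int = 100, test_fraction: float = 0.3,
                           seed: int = 0) -> PIResults:
    """Repeated-split permutation importance with CI gating.

    Each repetition draws a fresh grouped 70/30 split, fits the classifier
    with the supplied hyperparameters, computes the test AUROC, then
    permutes each feature's test column in turn (seeded) and records the
    AUROC drop. A repetition whose split is single-class on either side is
    resampled with a new seed (the event is counted in
    ``PIResults.base_scores`` length staying at ``n_reps``).
    """
    y = np.asarray(y).astype(int)
    groups = np.asarray(groups) if groups is not None else np.arange(len(y))
    model_params = model_params or {}
    features = list(X.columns)
    drops = np.zeros((n_reps, len(features)))
    base_scores = np.zeros(n_reps)

    rep = 0
    attempt = 0
    while rep < n_reps:
        split_seed = seed * 100003 + attempt
        attempt += 1
        if attempt > n_reps * 50:
            raise MetricError("could not draw two-class splits")
        train_idx, test_idx = grouped_split(groups, test_fraction, split_seed)
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            continue  # degenerate split: resample with a new seed
        clf = make_classifier(model_params, seed=split_seed)
        clf.fit(X.iloc[train_idx], y[train_idx])
        X_test = X.iloc[test_idx]
        base = auroc(clf.predict_proba(X_test)[:, 1], y[test_idx])
        base_scores[rep] = base
        rng = np.random.default_rng(split_seed + 1)
        for fi, feat in enumerate(features):
            permuted = X_test.copy()
            permuted[feat] = rng.permutation(permuted[feat].to_numpy())
            score = auroc(clf.predict_proba(permuted)[:, 1], y[test_idx])
            drops[rep, fi] = base - score
        rep += 1

    drop_df = pd.DataFrame(drops, columns=features)
    mean = drop_df.mean()
    lows, highs = {}, {}
    for feat in features:
        lo, hi = _t_ci(drop_df[feat].to_numpy())
        lows[feat], highs[feat] = lo, hi
    ci_low = pd.Series(lows)
    ci_high = pd.Series(highs)
    significant = ci_low > 0

    r_vals, p_vals = {}, {}
    for feat in features:
        r, p = spearman_sign(X[feat], y)
        r_vals[feat], p_vals[feat] = r, p
    return PIResults(drops=drop_df, mean_drop=mean, ci_low=ci_low,
                     ci_high=ci_high, significant=significant,
                     spearman_r=pd.Series(r_vals), spearman_p=pd.Series(p_vals),
                     base_scores=base_scores)


def significant_features(results: PIResults) -> list:
    """Features whose CI lower bound is strictly positive, sorted by mean
    drop descending (ties by name for determinism)."""
    sig = results.significant[results.significant].index
    ordered = sorted(sig, key=lambda f: (-results.mean_drop[f], f))
    return list(ordered)


def spearman_sign(feature, target):
    """Spearman rank correlation with the (binary) target and its
    two-sided p-value; (nan, nan) when the correlation is undefined."""
    x = np.asarray(feature, dtype=float)
    y = np.asarray(target, dtype=float)
    if x.size < 3:
        raise MetricError("Spearman needs at least 3 paired observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _battery_scores(X, y, groups, features, model_params, splits):
    scores = []
    for split_seed, (train_idx, test_idx) in splits:
        clf = make_classifier(model_params, seed=split_seed)
        clf.fit(X.iloc[train_idx][features], y[train_idx])
        p = clf.predict_proba(X.iloc[test_idx][features])[:, 1]
        scores.append(auroc(p, y[test_idx]))
    return float(np.mean(scores))


def backward_sfs(X: pd.DataFrame, y, groups=None, start_features=None,
                 model_params: dict | None = None, n_reps: int = 100,
                 test_fraction: float = 0.3, seed: int = 0) -> SFSTrace:
    """Backward sequential feature selection over a fixed split battery.

    At each step every candidate removal is scored by the mean AUROC over
    the same ``n_reps`` seeded grouped splits (paired comparisons); the
    argmax candidate is removed (ties by feature name order). The selected
    subset is the step with the highest mean score; score ties prefer the
    smaller subset.
    """
    y = np.asarray(y).astype(int)
    groups = np.asarray(groups) if groups is not None else np.arange(len(y))
    model_params = model_params or {}
    if not start_features:
        raise SelectionError("backward SFS needs a non-empty start set")
    current = sorted(start_features)
    if len(current) < 2:
        raise SelectionError("backward SFS needs at least two start features")

    # fixed battery of two-class grouped splits shared across all steps
    splits = []
    attempt = 0
    while len(splits) < n_reps:
        split_seed = seed * 100003 + attempt
        attempt += 1
        if attempt > n_reps * 50:
            raise MetricError("could not draw two-class splits")
        train_idx, test_idx = grouped_split(groups, test_fraction, split_seed)
        if len(np.unique(y[train_idx])) < 2 or len(np.unique(y[test_idx])) < 2:
            continue
        splits.append((split_seed, (train_idx, test_idx)))

    start_score = _battery_scores(X, y, groups, current, model_params, splits)
    removals = []
    step_sets = [(list(current), start_score)]
    while len(current) > 1:
        best = None
        for feat in current:  # lexicographic order -> deterministic ties
            candidate = [f for f in current if f != feat]
            score = _battery_scores(X, y, groups, candidate, model_params, splits)
            if best is None or score > best[1] + 1e-12:
                best = (feat, score)
        current = [f for f in current if f != best[0]]
        removals.append((best[0], best[1]))
        step_sets.append((list(current), best[1]))

    best_idx = 0
    for i, (_, score) in enumerate(step_sets[1:], start=1):
        if score > step_sets[best_idx][1] + 1e-12:
            best_idx = i
        elif abs(score - step_sets[best_idx][1]) <= 1e-12:
            best_idx = i  # score tie: prefer the smaller subset
    selected, selected_score = step_sets[best_idx]
    return SFSTrace(start_features=list(start_features), start_score=start_score,
                    removals=removals, selected=selected,
                    selected_score=selected_score)
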
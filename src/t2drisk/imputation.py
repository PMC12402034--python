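"""Per-feature imputer selection by Quality Score, and leakage-safe
application.

For each incomplete feature the module evaluates a menu of imputers —
univariate (median, mean, most frequent, distribution-preserving random)
and multivariate (k-NN with k = 5, iterative random-forest) — by masking a
held-out fraction of the *observed* entries, refilling them, and scoring
the reconstruction: an R²-type score for quantitative features (clipped at
0) or balanced accuracy for nominal ones. A discernibility gate rejects any
imputer whose imputed values are statistically distinguishable from the
held-out observed values (two-sample Kolmogorov-Smirnov test for
quantitative features, χ² for nominal, α = 0.05).

The winning imputer's score μ combines with the feature's completeness γ
into the Quality Score

    QS = γ + (1 − γ)·μ ∈ [γ, 1],

so a complete feature scores 1 (100%) regardless of μ, as does any feature
whose missing part is perfectly imputable. Features below the retention
threshold (default 0.7) are dropped. Imputers are always fitted on training
rows only and then applied to both train and test tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer, KNNImputer
from sklearn.metrics import balanced_accuracy_score, r2_score
from sklearn.neighbors import KNeighborsClassifier

from .errors import DataError, InputError

__all__ = [
    "ImputationConfig",
    "ImputerAssessment",
    "ImputationPlan",
    "classify_feature_type",
    "quality_score",
    "assess_imputer",
    "select_imputers",
    "apply_imputation",
    "one_hot_encode",
]

NOMINAL_IMPUTERS = ("most_frequent", "distribution_preserving_random",
                    "knn_k5", "iterative_rf")
QUANTITATIVE_IMPUTERS = ("median", "mean", "distribution_preserving_random",
                         "knn_k5", "iterative_rf")


@dataclass(frozen=True)
class ImputationConfig:
    retention_threshold: float = 0.7
    holdout_fraction: float = 0.2
    min_observed: int = 30
    alpha: float = 0.05
    nominal_min_frequency: int = 5
    nominal_max_levels: int = 15
    max_predictors: int = 15
    rf_estimators: int = 30
    rf_max_iter: int = 10


@dataclass
class ImputerAssessment:
    feature: str
    imputer_id: str
    gamma: float
    mu: float
    discernibility_pass: bool

    @property
    def qs(self) -> float:
        return quality_score(self.gamma, self.mu)


@dataclass
class ImputationPlan:
    """Per-feature chosen assessment (or None for complete/unimputable),
    typing, QS and retention flag."""

    entries: dict = field(default_factory=dict)  # feature -> dict
    config: ImputationConfig = field(default_factory=ImputationConfig)

    def retained_features(self) -> list[str]:
        return [f for f, e in self.entries.items() if e["retained"]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for feature, e in self.entries.items():
            rows.append(dict(feature=feature, imputer=e["imputer"],
                             typing=e["typing"], gamma=e["gamma"], mu=e["mu"],
                             qs=e["qs"], retained=e["retained"]))
        return pd.DataFrame(rows).set_index("feature")

    def to_json(self, path) -> None:
        import json
        self.to_frame().reset_index().to_json(path, orient="records", indent=1)
        _ = json  # noqa


def classify_feature_type(values, config: ImputationConfig = ImputationConfig()) -> str:
    """'nominal' iff every distinct observed value occurs at least
    ``nominal_min_frequency`` times (χ²-test validity rule) and the number
    of levels is small; 'quantitative' otherwise."""
    x = pd.Series(values).dropna()
    if x.empty:
        raise InputError("cannot type a feature with no observed values")
    if not pd.api.types.is_numeric_dtype(x):
        try:
            x = x.astype(float)
        except (TypeError, ValueError) as exc:
            raise DataError("non-numeric values in feature column") from exc
    counts = x.value_counts()
    if (len(counts) <= config.nominal_max_levels
            and (counts >= config.nominal_min_frequency).all()):
        return "nominal"
    return "quantitative"


def quality_score(gamma: float, mu: float) -> float:
    """QS = γ + (1 − γ)·μ."""
    if not (0.0 <= gamma <= 1.0) or not (0.0 <= mu <= 1.0):
        raise InputError("gamma and mu must lie in [0, 1]")
    return gamma + (1.0 - gamma) * mu


def one_hot_encode(df: pd.DataFrame, nominal_columns) -> pd.DataFrame:
    """One-hot expansion of nominal predictor columns (NaN -> all-zero row
    for that feature's indicators)."""
    out = []
    for col in df.columns:
        if col in nominal_columns:
            dummies = pd.get_dummies(df[col], prefix=col, dtype=float)
            out.append(dummies)
        else:
            out.append(df[[col]].astype(float))
    return pd.concat(out, axis=1)


class _PredictorPrep:
    """Completeness-ranked predictor cap with train-learned univariate
    pre-fill and one-hot encoding; fill statistics are fitted once on the
    training predictors and reused verbatim on any later rows."""

    def __init__(self, types: dict, config: ImputationConfig):
        self.types = types
        self.config = config
        self.keep: list[str] = []
        self.fills: dict[str, float] = {}
        self.nominal: set[str] = set()
        self.columns = None

    def fit(self, predictors: pd.DataFrame) -> "_PredictorPrep":
        completeness = predictors.notna().mean().sort_values(ascending=False)
        self.keep = list(completeness.index[: self.config.max_predictors])
        self.nominal = {c for c in self.keep if self.types.get(c) == "nominal"}
        for c in self.keep:
            if c in self.nominal:
                mode = predictors[c].mode(dropna=True)
                self.fills[c] = float(mode.iloc[0]) if len(mode) else 0.0
            else:
                med = predictors[c].median(skipna=True)
                self.fills[c] = 0.0 if pd.isna(med) else float(med)
        self.columns = self.transform(predictors).columns
        return self

    def transform(self, predictors: pd.DataFrame) -> pd.DataFrame:
        sub = predictors[self.keep].copy()
        for c in self.keep:
            sub[c] = sub[c].fillna(self.fills[c])
        encoded = one_hot_encode(sub, self.nominal)
        if self.columns is not None:
            encoded = encoded.reindex(columns=self.columns, fill_value=0.0)
        return encoded


class _Imputer:
    """Minimal fit/predict interface for one target feature."""

    def __init__(self, imputer_id: str, typing: str, config: ImputationConfig,
                 seed: int):
        self.imputer_id = imputer_id
        self.typing = typing
        self.config = config
        self.seed = seed
        self._stat = None
        self._model = None
        self._observed = None

    def fit(self, target: pd.Series, predictors: pd.DataFrame | None,
            types: dict | None = None) -> "_Imputer":
        obs = target.dropna()
        cfg = self.config
        if self.imputer_id == "median":
            self._stat = float(obs.median())
        elif self.imputer_id == "mean":
            self._stat = float(obs.mean())
        elif self.imputer_id == "most_frequent":
            mode = obs.mode()
            self._stat = float(mode.iloc[0]) if len(mode) else float("nan")
        elif self.imputer_id == "distribution_preserving_random":
            self._observed = obs.to_numpy(dtype=float)
        elif self.imputer_id in ("knn_k5", "iterative_rf"):
            if predictors is None or predictors.shape[1] == 0:
                raise DataError("multivariate imputer needs predictor columns")
            self._prep = _PredictorPrep(types or {}, cfg).fit(
                predictors.loc[target.index])
            X = self._prep.transform(predictors.loc[target.index])
            fit_rows = obs.index
            if self.imputer_id == "knn_k5":
                if self.typing == "nominal":
                    model = KNeighborsClassifier(n_neighbors=min(5, len(fit_rows)))
                    model.fit(X.loc[fit_rows], obs.astype(int))
                else:
                    # KNNImputer on [target | predictors]: the sklearn-native
                    # k-NN imputation path
                    mat = pd.concat([target.rename("__target__"), X], axis=1)
                    model = KNNImputer(n_neighbors=5)
                    model.fit(mat.loc[fit_rows])
                    self._mat_columns = mat.columns
            else:  # iterative_rf
                if self.typing == "nominal":
                    model = RandomForestClassifier(
                        n_estimators=cfg.rf_estimators, max_depth=8,
                        random_state=self.seed)
                    model.fit(X.loc[fit_rows], obs.astype(int))
                else:
                    est = RandomForestRegressor(
                        n_estimators=cfg.rf_estimators, max_depth=8,
                        random_state=self.seed)
                    mat = pd.concat([target.rename("__target__"), X], axis=1)
                    model = IterativeImputer(
                        estimator=est, max_iter=cfg.rf_max_iter,
                        random_state=self.seed, sample_posterior=False,
                        skip_complete=True)
                    # fit on ALL rows: the imputer only learns a model for
                    # columns that are incomplete during fit
                    model.fit(mat)
                    self._mat_columns = mat.columns
            self._model = model
        else:
            raise InputError(f"unknown imputer {self.imputer_id!r}")
        return self

    def predict(self, index, target: pd.Series | None = None,
                predictors: pd.DataFrame | None = None,
                types: dict | None = None) -> np.ndarray:
        """Imputed values for the rows in ``index``."""
        n = len(index)
        if self.imputer_id in ("median", "mean", "most_frequent"):
            return np.full(n, self._stat)
        if self.imputer_id == "distribution_preserving_random":
            rng = np.random.default_rng(self.seed)
            return rng.choice(self._observed, size=n, replace=True)
        X = self._prep.transform(predictors.loc[index])
        if self.typing == "nominal":
            return self._model.predict(X).astype(float)
        tgt = pd.Series(np.nan, index=X.index, name="__target__")
        mat = pd.concat([tgt, X], axis=1)[self._mat_columns]
        filled = self._model.transform(mat)
        return filled[:, list(self._mat_columns).index("__target__")]


def assess_imputer(feature: pd.Series, predictors: pd.DataFrame | None,
                   imputer_id: str, seed: int,
                   typing: str | None = None,
                   types: dict | None = None,
                   config: ImputationConfig = ImputationConfig()) -> ImputerAssessment:
    """Score one imputer on one feature by masked-holdout reconstruction.

    A complete feature short-circuits to γ = 1, QS = 1, imputer 'none'. A
    failed fit is recorded as μ = 0 with the discernibility gate failed.
    """
    name = str(feature.name) if feature.name is not None else "feature"
    gamma = float(feature.notna().mean())
    if gamma >= 1.0:
        return ImputerAssessment(name, "none", 1.0, 0.0, True)
    observed_idx = feature.dropna().index
    if len(observed_idx) < config.min_observed:
        return ImputerAssessment(name, imputer_id, gamma, 0.0, False)
    typing = typing or classify_feature_type(feature, config)

    rng = np.random.default_rng(seed)
    n_hold = max(1, int(round(config.holdout_fraction * len(observed_idx))))
    held = pd.Index(rng.choice(observed_idx.to_numpy(), size=n_hold, replace=False))
    masked = feature.copy()
    masked.loc[held] = np.nan

    try:
        imp = _Imputer(imputer_id, typing, config, seed).fit(masked, predictors, types)
        predicted = imp.predict(held, target=masked, predictors=predictors,
                                types=types)
    except Exception:
        return ImputerAssessment(name, imputer_id, gamma, 0.0, False)

    truth = feature.loc[held].to_numpy(dtype=float)
    if typing == "nominal":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # unseen-level warnings are expected
            mu = float(balanced_accuracy_score(truth.astype(int),
                                               np.asarray(predicted).astype(int)))
    else:
        if np.var(truth) == 0:
            mu = 1.0 if np.allclose(predicted, truth) else 0.0
        else:
            mu = float(r2_score(truth, predicted))
    mu = float(np.clip(mu, 0.0, 1.0))

    discernible = _discernibility_reject(truth, np.asarray(predicted, dtype=float),
                                         typing, config.alpha)
    return ImputerAssessment(name, imputer_id, gamma, mu, not discernible)


def _discernibility_reject(observed: np.ndarray, imputed: np.ndarray,
                           typing: str, alpha: float) -> bool:
    """True iff imputed values are statistically discernible from observed."""
    if typing == "nominal":
        levels = np.union1d(observed, imputed)
        obs_counts = np.array([(observed == l).sum() for l in levels], dtype=float)
        imp_counts = np.array([(imputed == l).sum() for l in levels], dtype=float)
        table = np.vstack([obs_counts, imp_counts])
        keep = table.sum(axis=0) > 0
        table = table[:, keep]
        if table.shape[1] < 2:
            return False  # single shared level: indistinguishable
        try:
            _, p, _, _ = stats.chi2_contingency(table)
        except ValueError:
            return False
        return bool(p < alpha)
    if np.var(observed) == 0 and np.var(imputed) == 0:
        return not np.allclose(observed.mean(), imputed.mean())
    _, p = stats.ks_2samp(observed, imputed)
    return bool(p < alpha)


def select_imputers(table: pd.DataFrame, seed: int = 0,
                    config: ImputationConfig = ImputationConfig(),
                    types: dict | None = None) -> ImputationPlan:
    """Build an imputation plan on a *training* table.

    For each incomplete feature: assess all applicable imputers, discard
    those failing the discernibility gate, pick the highest μ among
    survivors; retained iff QS >= threshold. If every imputer is rejected,
    QS falls back to γ alone and — when still retained — the
    distribution-preserving random imputer fills the holes (the least
    distribution-distorting fallback).
    """
    plan = ImputationPlan(config=config)
    types = dict(types or {})
    for col in table.columns:
        if col not in types:
            types[col] = classify_feature_type(table[col], config)
    for col in table.columns:
        feat = table[col]
        gamma = float(feat.notna().mean())
        typing = types[col]
        if gamma >= 1.0:
            plan.entries[col] = dict(imputer="none", typing=typing, gamma=1.0,
                                     mu=0.0, qs=1.0, retained=True)
            continue
        menu = NOMINAL_IMPUTERS if typing == "nominal" else QUANTITATIVE_IMPUTERS
        predictors = table.drop(columns=[col])
        assessments = [
            assess_imputer(feat, predictors, imp, seed=seed, typing=typing,
                           types=types, config=config)
            for imp in menu
        ]
        survivors = [a for a in assessments if a.discernibility_pass]
        if survivors:
            best = max(survivors, key=lambda a: (a.mu, a.imputer_id))
            qs = best.qs
            imputer = best.imputer_id
            mu = best.mu
        else:
            qs = gamma
            mu = 0.0
            imputer = "distribution_preserving_random"
        retained = qs >= config.retention_threshold
        plan.entries[col] = dict(imputer=imputer, typing=typing, gamma=gamma,
                                 mu=mu, qs=qs, retained=retained)
    return plan


def apply_imputation(plan: ImputationPlan, train: pd.DataFrame,
                     test: pd.DataFrame | None = None, seed: int = 0):
    """Fill retained features in train (and test) using train-fitted
    imputers; drop non-retained features from both tables."""
    missing = set(plan.entries) - set(train.columns)
    if missing:
        raise DataError(f"plan features absent from table: {sorted(missing)[:5]}")
    retained = plan.retained_features()
    types = {f: plan.entries[f]["typing"] for f in plan.entries}
    train_out = train[retained].copy()
    test_out = test[retained].copy() if test is not None else None

    for col in retained:
        entry = plan.entries[col]
        if entry["imputer"] == "none" and not train_out[col].isna().any():
            if test_out is not None and test_out[col].isna().any():
                entry = dict(entry, imputer="median"
                             if entry["typing"] == "quantitative" else "most_frequent")
            else:
                continue
        imp = _Imputer(entry["imputer"], entry["typing"], plan.config,
                       seed=seed + _col_offset(col))
        predictors = train.drop(columns=[col])
        imp.fit(train[col], predictors, types)
        for tbl, full in ((train_out, train), (test_out, test)):
            if tbl is None:
                continue
            holes = tbl.index[tbl[col].isna()]
            if len(holes):
                preds = full.drop(columns=[col])
                tbl.loc[holes, col] = imp.predict(holes, target=full[col],
                                                  predictors=preds, types=types)
    if test_out is not None:
        return train_out, test_out
    return train_out


def _col_offset(col: str) -> int:
    import hashlib
    return int.from_bytes(hashlib.sha256(col.encode()).digest()[:2], "big")
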
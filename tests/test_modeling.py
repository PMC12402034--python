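"""AUROC, Youden-threshold metrics, grouped cross-validation, TPE tuning
and partial dependence."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import t2drisk as t
from t2drisk.errors import ConfigurationError, InputError, MetricError
from t2drisk.modeling import IntUniform, LogUniform, Uniform
from tests.conftest import TINY_PARAMS


def auroc_bruteforce(scores, labels):
    """Exhaustive positive-negative pair count with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p, q in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestAUROC:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
        ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),
        ([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], 0.75),
    ])
    def test_known_values(self, scores, labels, expected):
        assert t.auroc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            t.auroc([0.1, 0.9], [1, 1])

    @given(st.lists(
        st.tuples(st.floats(0, 1, allow_nan=False), st.integers(0, 1)),
        min_size=2, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_equals_bruteforce_oracle(self, pairs):
        scores = [s for s, _ in pairs]
        labels = [y for _, y in pairs]
        if len(set(labels)) < 2:
            return
        assert t.auroc(scores, labels) == \
            pytest.approx(auroc_bruteforce(scores, labels))


class TestYoudenMetrics:
    def test_printed_j_identity(self):
        """TPR 0.87 with TNR 0.72 yields J = 0.59 at the chosen cutoff."""
        assert 0.87 + 0.72 - 1 == pytest.approx(0.59)

    def test_perfect_separation(self):
        m = t.youden_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert m.tpr == m.tnr == m.j == 1.0 and m.f1 == 1.0

    def test_identities_hold_at_every_threshold(self, rng):
        scores = rng.random(60)
        labels = rng.integers(0, 2, 60)
        y = np.asarray(labels)
        n_pos, n_neg = y.sum(), (1 - y).sum()
        for thr in np.unique(scores):
            pred = scores >= thr
            tp = (pred & (y == 1)).sum()
            fp = (pred & (y == 0)).sum()
            tpr, tnr = tp / n_pos, (n_neg - fp) / n_neg
            ppv = tp / (tp + fp) if tp + fp else 0.0
            j = tpr + tnr - 1
            assert j == pytest.approx(tpr - (1 - tnr))
            if tpr + ppv:
                f1 = 2 * tpr * ppv / (tpr + ppv)
                assert 0 <= f1 <= 1
        m = t.youden_metrics(scores, labels)
        assert m.j == pytest.approx(m.tpr + m.tnr - 1)
        if m.tpr + m.ppv:
            assert m.f1 == pytest.approx(2 * m.tpr * m.ppv / (m.tpr + m.ppv))

    def test_tie_takes_lowest_threshold(self):
        # two thresholds achieve the same J; the lower one is reported
        m = t.youden_metrics([0.1, 0.2, 0.8, 0.9], [0, 1, 1, 1])
        assert m.threshold == pytest.approx(0.2)

    def test_single_class_rejected(self):
        with pytest.raises(MetricError):
            t.youden_metrics([0.5, 0.6], [0, 0])


class TestCrossvalEvaluate:
    def test_partition_and_perfect_separation(self, rng):
        n = 200
        y = rng.integers(0, 2, n)
        # the only informative feature is class-constant, so every learned
        # split separates held-out folds perfectly
        X = pd.DataFrame({"noise": rng.normal(size=n),
                          "margin": np.where(y == 1, 50.0, -50.0)})
        groups = rng.integers(0, 25, n)
        params = {**TINY_PARAMS, "subsample": 1.0, "colsample_bytree": 1.0}
        ev = t.crossval_evaluate(X, y, groups, params, k=5, seed=0)
        assert ev.mean_auroc == pytest.approx(1.0)
        assert ev.ci[1] - ev.ci[0] == pytest.approx(0.0, abs=1e-9)

    def test_label_permutation_near_chance(self, rng):
        n = 500
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = rng.permutation(np.r_[np.ones(250), np.zeros(250)]).astype(int)
        groups = rng.integers(0, 25, n)
        scores = []
        for seed in range(5):
            ev = t.crossval_evaluate(X, y, groups, TINY_PARAMS, k=5, seed=seed)
            scores.append(ev.mean_auroc)
        assert np.mean(scores) == pytest.approx(0.5, abs=0.05)

    def test_group_disjoint_folds(self, rng):
        from t2drisk.modeling import _grouped_stratified_folds
        y = rng.integers(0, 2, 300)
        groups = rng.integers(0, 30, 300)
        folds, _ = _grouped_stratified_folds(y, groups, 5, seed=0)
        seen = []
        for _, test_idx in folds:
            test_groups = set(groups[test_idx])
            for prior in seen:
                assert test_groups.isdisjoint(prior)
            seen.append(test_groups)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(300))


class TestTuneHyperparameters:
    SPACE = {
        "n_estimators": IntUniform(10, 40, default=20),
        "learning_rate": LogUniform(0.05, 0.3, default=0.1),
        "subsample": Uniform(0.6, 1.0, default=0.9),
    }

    def test_single_point_space_returned(self, toy_classification):
        X, y, groups = toy_classification
        space = {"max_depth": IntUniform(3, 3, default=3)}
        got = t.tune_hyperparameters(X, y, groups, space, n_folds=3,
                                     n_trials=3, seed=0)
        assert got.params["max_depth"] == 3

    def test_deterministic_given_seed(self, toy_classification):
        X, y, groups = toy_classification
        a = t.tune_hyperparameters(X, y, groups, self.SPACE, n_folds=3,
                                   n_trials=8, seed=5)
        b = t.tune_hyperparameters(X, y, groups, self.SPACE, n_folds=3,
                                   n_trials=8, seed=5)
        assert a.params == b.params and a.score == b.score

    def test_never_below_default_point(self, toy_classification):
        """Trial 0 evaluates the declared default, so the tuned score is at
        least the default-parameter score on the same folds."""
        from t2drisk.modeling import _cv_auroc
        X, y, groups = toy_classification
        got = t.tune_hyperparameters(X, y, groups, self.SPACE, n_folds=3,
                                     n_trials=6, seed=1)
        default_score = _cv_auroc(
            X, np.asarray(y), np.asarray(groups),
            {"n_estimators": 20, "learning_rate": 0.1, "subsample": 0.9},
            3, seed=1)
        assert got.score >= default_score - 1e-12

    def test_empty_space_rejected(self, toy_classification):
        X, y, groups = toy_classification
        with pytest.raises(ConfigurationError):
            t.tune_hyperparameters(X, y, groups, {}, n_trials=2)


class TestPartialDependence:
    def test_model_ignoring_feature_gives_flat_curve(self, rng):
        class OnlyFirst:
            def predict_proba(self, df):
                p = 1 / (1 + np.exp(-df["a"].to_numpy()))
                return np.c_[1 - p, p]

        table = pd.DataFrame({"a": rng.normal(size=50),
                              "b": rng.normal(size=50)})
        curve = t.partial_dependence(OnlyFirst(), table, "b")
        assert np.ptp(curve.response) == pytest.approx(0.0, abs=1e-12)

    def test_identity_model_reproduces_grid(self, rng):
        class Identity:
            def predict(self, df):
                return df["a"].to_numpy()

        table = pd.DataFrame({"a": rng.uniform(0, 1, 50)})
        grid = np.linspace(0.1, 0.9, 9)
        curve = t.partial_dependence(Identity(), table, "a", grid=grid)
        np.testing.assert_allclose(curve.response, grid)

    def test_additive_model_recovers_component(self, rng):
        class Additive:
            def predict(self, df):
                return np.sin(df["a"].to_numpy()) + df["b"].to_numpy() ** 2

        table = pd.DataFrame({"a": rng.uniform(-2, 2, 80),
                              "b": rng.uniform(-1, 1, 80)})
        grid = np.linspace(-1.5, 1.5, 25)
        curve = t.partial_dependence(Additive(), table, "a", grid=grid)
        # equal to sin(grid) up to the additive constant E[b^2]
        centered = curve.response - curve.response.mean()
        expected = np.sin(grid) - np.sin(grid).mean()
        np.testing.assert_allclose(centered, expected, atol=1e-9)

    def test_group_curves_split_by_label(self, rng):
        class Mean:
            def predict(self, df):
                return df.mean(axis=1).to_numpy()

        table = pd.DataFrame({"a": rng.normal(size=40),
                              "b": rng.normal(size=40)})
        labels = rng.integers(0, 2, 40)
        curve = t.partial_dependence(Mean(), table, "a",
                                     grid=np.linspace(-1, 1, 5),
                                     group_labels=labels)
        assert set(curve.group_curves) == {0, 1}

    def test_unknown_feature_rejected(self, rng):
        table = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(InputError):
            t.partial_dependence(None, table, "zzz")

    def test_monotone_model_monotone_curve(self, rng):
        """A single-feature monotone-constrained booster yields a
        nondecreasing partial-dependence curve on monotone data."""
        n = 300
        x = rng.uniform(0, 1, n)
        y = (x + 0.1 * rng.normal(size=n) > 0.5).astype(int)
        X = pd.DataFrame({"x": x})
        model = t.make_classifier(
            {**TINY_PARAMS, "monotone_constraints": "(1)"}, seed=0)
        model.fit(X, y)
        curve = t.partial_dependence(model, X, "x",
                                     grid=np.linspace(0.05, 0.95, 20))
        assert (np.diff(curve.response) >= -1e-9).all()
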
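"""Synthetic cohort generator: determinism, exact label counts, label
consistency, municipality structure and missingness mechanisms."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import t2drisk as t
from t2drisk.errors import ConfigurationError
from t2drisk.modeling import auroc


class TestMunicipalityTable:
    def test_default_counts_and_coverage(self, default_config):
        table = t.generate_municipality_table(default_config)
        assert len(table) == 319
        assert int(table["covered"].sum()) == 56
        covered = table[table["covered"]]
        for col in [c for c in table.columns if c.startswith("pollution_")]:
            assert covered[col].map(len).eq(10).all()
            assert table.loc[~table["covered"], col].isna().all()

    def test_full_coverage_boundary(self):
        cfg = replace(t.CohortConfig.smoke(), n_covered_municipalities=30)
        table = t.generate_municipality_table(cfg)
        assert table["covered"].all()

    def test_income_missing_fraction(self, default_config):
        table = t.generate_municipality_table(default_config)
        assert int(table["income"].isna().sum()) == round(0.2 * 319)

    def test_deterministic_given_seed(self, smoke_config):
        a = t.generate_municipality_table(smoke_config)
        b = t.generate_municipality_table(smoke_config)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            t.CohortConfig(n_individuals=0)
        with pytest.raises(ConfigurationError):
            t.CohortConfig(n_covered_municipalities=400)


class TestGenerateCohort:
    def test_default_size(self, raw_default_bundle):
        assert raw_default_bundle.n_individuals == 4617

    def test_label_counts_exact(self, raw_default_bundle, default_config):
        labels = raw_default_bundle.labels
        assert int(labels["known_t2d"].sum()) == default_config.n_known_t2d
        assert int(labels["baseline_new_diagnosis"].sum()) == 227
        assert int(labels["in_followup"].sum()) == 1850
        assert int(labels["incident_t2d"].sum()) == 125

    def test_label_consistency(self, raw_default_bundle):
        lab = raw_default_bundle.labels
        inc = lab["incident_t2d"]
        assert (lab.loc[inc, "in_followup"]).all()
        assert (lab.loc[inc, "followup_complete"]).all()
        assert not lab.loc[inc, "known_t2d"].any()
        assert not lab.loc[inc, "baseline_new_diagnosis"].any()
        assert raw_default_bundle.municipality_id.notna().all()
        # follow-up years stored exactly for follow-up members
        assert lab.loc[lab["in_followup"], "followup_years"].notna().all()
        assert lab.loc[~lab["in_followup"], "followup_years"].isna().all()

    def test_mask_matches_presence(self, smoke_bundle):
        assert (smoke_bundle.mask == smoke_bundle.values.notna()).all().all()

    def test_determinism_byte_identical(self, smoke_config):
        a = t.generate_cohort(smoke_config)
        b = t.generate_cohort(smoke_config)
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.labels, b.labels)
        pd.testing.assert_series_equal(a.municipality_id, b.municipality_id)

    def test_unknown_effect_feature_rejected(self):
        cfg = replace(t.CohortConfig.smoke(),
                      effect_spec=(t.EffectSpec("not_a_feature", 1, 1.0),))
        with pytest.raises(ConfigurationError):
            t.generate_cohort(cfg)

    def test_null_effects_give_chance_models(self):
        """With all effect magnitudes zero, labels are independent of the
        features: repeated-cohort AUROC of a fitted model stays near 0.5."""
        from t2drisk.pipeline import TaskSpec, build_task_sample
        from t2drisk.modeling import crossval_evaluate
        from tests.conftest import TINY_PARAMS

        scores = []
        for seed in range(20):
            cfg = replace(
                t.CohortConfig.smoke(seed=seed),
                n_individuals=600, n_known_t2d=50, n_new_diagnosis=60,
                n_followup=250, n_followup_eligible=200, n_incident=20,
                n_followup_known_t2d=25, n_followup_baseline_cases=15,
                effect_spec=tuple(replace(e, magnitude=0.0)
                                  for e in t.CohortConfig().effect_spec))
            bundle = t.generate_cohort(cfg)
            X, y, groups = build_task_sample(bundle, TaskSpec("diagnosis", "HEA"))
            X = X[["age", "bmi", "fasting_glucose"]].fillna(0.0)
            ev = crossval_evaluate(X, y, groups, TINY_PARAMS, k=5, seed=seed)
            scores.append(ev.mean_auroc)
        assert abs(np.mean(scores) - 0.5) < 0.05

    def test_dominant_driver_tops_univariate_auroc(self):
        """A single overwhelming clinical driver has the best univariate
        AUROC of any feature (brute-force scan)."""
        cfg = replace(t.CohortConfig.smoke(seed=11),
                      effect_spec=(t.EffectSpec("fasting_glucose", 1, 5.0),),
                      latent_noise_sd=0.3)
        bundle = t.generate_cohort(cfg)
        y = bundle.labels["baseline_new_diagnosis"].astype(int)
        best_feat, best_score = None, -1.0
        for col in bundle.values.columns:
            x = bundle.values[col].to_numpy(dtype=float)
            if np.unique(x[~np.isnan(x)]).size < 2:
                continue
            score = auroc(np.nan_to_num(x), y)
            score = max(score, 1 - score)
            if score > best_score:
                best_feat, best_score = col, score
        assert best_feat == "fasting_glucose"

    def test_default_drivers_in_top_decile(self, raw_default_bundle,
                                           default_config):
        """Planted drivers rank in the top decile of univariate AUROC."""
        bundle = raw_default_bundle
        y = bundle.labels["baseline_new_diagnosis"].astype(int)
        keep = ~bundle.labels["known_t2d"]
        scores = {}
        for col in bundle.values.columns:
            x = bundle.values.loc[keep, col].to_numpy(dtype=float)
            if np.unique(x[~np.isnan(x)]).size < 2:
                continue
            s = auroc(np.nan_to_num(x), y[keep])
            scores[col] = max(s, 1 - s)
        ranked = sorted(scores, key=scores.get, reverse=True)
        decile = set(ranked[: max(1, len(ranked) // 10)])
        for eff in default_config.effect_spec:
            assert eff.feature in decile, f"driver {eff.feature} not in top decile"


class TestInjectMissingness:
    def test_zero_rates_leave_mask_unchanged(self, smoke_config):
        bundle = t.generate_cohort(smoke_config)
        cfg = replace(
            smoke_config,
            n_covered_municipalities=smoke_config.n_municipalities,
            income_missing_fraction=0.0, uncovered_resident_fraction=0.0,
            missingness_spec=t.MissingnessSpec(mcar_rates={}, block_rates={}))
        full = t.generate_cohort(cfg)
        out = t.inject_missingness(full, cfg)
        pd.testing.assert_frame_equal(out.mask, full.mask)

    def test_geospatial_missingness_tracks_coverage(self, default_config):
        bundle = t.generate_cohort(default_config)
        out = t.inject_missingness(bundle, default_config)
        covered = (out.municipalities.set_index("municipality_id")["covered"]
                   .reindex(out.municipality_id).to_numpy())
        pol = [c for c in out.values.columns if c.startswith("pollution_")]
        assert out.mask.loc[~covered, pol].eq(False).all().all()
        assert out.mask.loc[covered, pol].eq(True).all().all()
        # ~50.4% of individuals lack pollution values under the default config
        assert 1 - out.mask[pol[0]].mean() == pytest.approx(0.504, abs=0.01)

    def test_block_rate_one_wipes_whole_block(self, smoke_config):
        bundle = t.generate_cohort(smoke_config)
        cfg = replace(smoke_config,
                      missingness_spec=t.MissingnessSpec(
                          mcar_rates={}, block_rates={"ffq": 1.0}))
        out = t.inject_missingness(bundle, cfg)
        ffq = out.metadata.index[out.metadata["block"] == "ffq"]
        patterns = out.mask[list(ffq)]
        assert not patterns.any().any()

    def test_block_missingness_identical_within_block(self, smoke_bundle):
        meta = smoke_bundle.metadata
        ffq = list(meta.index[meta["block"] == "ffq"])
        base = smoke_bundle.mask[ffq[0]]
        for col in ffq[1:]:
            # block wipe is individual-level; differences only via MCAR
            joint_missing = ~smoke_bundle.mask[col] & ~base
            assert joint_missing.sum() > 0

    def test_bad_rate_rejected(self, smoke_config):
        bundle = t.generate_cohort(smoke_config)
        cfg = replace(smoke_config,
                      missingness_spec=t.MissingnessSpec(
                          mcar_rates={"lifestyle": 1.5}, block_rates={}))
        with pytest.raises(ConfigurationError):
            t.inject_missingness(bundle, cfg)

    def test_unknown_block_rejected(self, smoke_config):
        bundle = t.generate_cohort(smoke_config)
        cfg = replace(smoke_config,
                      missingness_spec=t.MissingnessSpec(
                          mcar_rates={}, block_rates={"nonexistent": 0.5}))
        with pytest.raises(ConfigurationError):
            t.inject_missingness(bundle, cfg)


def test_save_roundtrip(tmp_path, smoke_bundle):
    smoke_bundle.save(tmp_path)
    assert (tmp_path / "cohort.csv").exists()
    assert (tmp_path / "metadata.json").exists()
    reloaded = pd.read_csv(tmp_path / "cohort.csv", index_col="individual")
    assert reloaded.shape == smoke_bundle.values.shape
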
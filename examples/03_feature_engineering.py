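"""Collapse the raw questionnaire layer into engineered features.

Mixed day/week/month food-frequency items are standardized to monthly
counts, semantic groups are summed into representative features, smoking
sub-questions become pack-years, waist/hip becomes a ratio, and
threshold-derived flags (e.g. an obesity flag computable from BMI) are
dropped.
"""

import t2drisk as t

print("2 per day as monthly count:", t.normalize_frequency(2, "day"))   # 60
print("30 years at 20 cigarettes/day:",
      t.smoking_pack_years(30, 20), "pack-years")                       # 30
print("waist 90 / hip 100:", t.waist_hip_ratio(90, 100))                # 0.9

cfg = t.CohortConfig(seed=1)
bundle = t.inject_missingness(t.generate_cohort(cfg), cfg)
bundle = t.augment_cohort_geospatial(bundle)
print("raw feature columns:", bundle.values.shape[1])

engineered = t.engineer_features(bundle)
env = engineered.feature_names("ENV")
cli = engineered.feature_names("CLI")
print(f"after engineering: {len(env)} environmental + {len(cli)} clinical "
      f"features ({engineered.values.shape[1]} total)")
print("source breakdown:")
print(engineered.metadata["source"].value_counts().to_string())
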
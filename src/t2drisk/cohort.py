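"""Synthetic cohort generator.

Emulates the structure of a population-based type 2 diabetes (T2D) study:
a baseline questionnaire-heavy feature layer (food-frequency items reported
in mixed day/week/month periods, smoking sub-questions, anthropometrics,
disease and treatment flags, clinical biochemistry), municipality links to a
geospatial table with partial pollution coverage, block-structured
missingness, and binary outcomes for two tasks — T2D newly diagnosed at
baseline (diagnosis) and incident T2D over a ~7.5-year follow-up
(prognosis).

Labels are driven by a latent linear risk score over configured driver
features and assigned by *exact-count thresholding*: the configured number
of positives is selected as the top of the latent score (seed-stable tie
break), so cohort composition counts are deterministic and exact rather
than binomial draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import hashlib
import json

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "EffectSpec",
    "FeatureInventory",
    "MissingnessSpec",
    "CohortConfig",
    "CohortBundle",
    "generate_municipality_table",
    "generate_cohort",
    "inject_missingness",
]

POLLUTION_METRIC_NAMES = [
    "no2", "so2", "o3", "pm10", "pm25", "co",
    "arsenic", "nickel", "cadmium", "lead", "benzene", "bap",
]

CLINICAL_FEATURES = [
    "fasting_glucose", "hba1c", "triglycerides", "total_cholesterol",
    "hdl_cholesterol", "ldl_cholesterol", "aspartate_transaminase",
    "alanine_transaminase", "gamma_glutamyl_transferase", "fasting_insulin",
    "creatinine", "uric_acid", "c_reactive_protein", "tsh", "ferritin",
    "albumin",
]

# lifestyle items retained as individual features (not grouped away);
# FFQ-style ones carry a declared reporting period
NAMED_SINGLES = [
    ("physical_activity_workdays", None),
    ("hours_of_sleep", None),
    ("walking_met_minutes_week", None),
    ("moderate_met_minutes_week", None),
    ("vigorous_met_minutes_week", None),
    ("t2d_relatives_first_degree", None),
    ("t2d_relatives_second_degree", None),
    ("sugar_soft_drinks", "week"),
    ("sugar_free_soft_drinks", "week"),
    ("meat_intake", "week"),
    ("fresh_fish_seafood_intake", "week"),
    ("fruit_intake", "day"),
]


@dataclass(frozen=True)
class EffectSpec:
    """One latent-risk driver: feature name, direction (+1/-1), magnitude
    on the log-odds scale applied to the standardized feature."""

    feature: str
    direction: int
    magnitude: float


@dataclass(frozen=True)
class FeatureInventory:
    """Raw questionnaire expansion: how many source items feed each
    semantic food group, and how many lifestyle items stay individual."""

    ffq_group_sources: dict = field(default_factory=lambda: {
        "tea_and_infusions": 6,
        "coffee": 8,
        "caffeinated_extra": 6,
        "wine": 5,
        "alcohol_extra": 7,
        "vegetables_legumes": 20,
        "fried_precooked": 14,
        "eggs_dairy": 16,
        "carbohydrate_rich": 24,
        "sugar_snacks_desserts": 40,
        "fatty_sides": 34,
    })
    n_wholegrain_sources: int = 8  # subset of carbohydrate_rich sources
    n_lifestyle_singles: int = 37


@dataclass(frozen=True)
class MissingnessSpec:
    """Rates for the three missingness mechanisms: per-source MCAR,
    individual-level block wipes, and coverage-driven geospatial holes."""

    mcar_rates: dict = field(default_factory=lambda: {
        "lifestyle": 0.02,
        "anthropometric": 0.02,
        "disease": 0.01,
        "clinical": 0.05,
    })
    block_rates: dict = field(default_factory=lambda: {
        "ffq": 0.12,
        "exercise": 0.10,
    })


@dataclass(frozen=True)
class CohortConfig:
    n_individuals: int = 4617
    n_known_t2d: int = 417
    n_new_diagnosis: int = 227
    n_followup: int = 1850
    n_followup_eligible: int = 1608
    n_incident: int = 125
    n_followup_known_t2d: int = 100
    n_followup_baseline_cases: int = 80
    n_municipalities: int = 319
    n_covered_municipalities: int = 56
    n_regions: int = 15
    n_pollution_metrics: int = 12
    n_pollution_years: int = 10
    income_missing_fraction: float = 0.2
    uncovered_resident_fraction: float = 0.504
    followup_years_mean: float = 7.48
    followup_years_sd: float = 0.55
    feature_inventory: FeatureInventory = field(default_factory=FeatureInventory)
    missingness_spec: MissingnessSpec = field(default_factory=MissingnessSpec)
    effect_spec: tuple = (
        EffectSpec("fasting_glucose", +1, 1.6),
        EffectSpec("age", +1, 0.9),
        EffectSpec("bmi", +1, 0.7),
        EffectSpec("t2d_relatives_first_degree", +1, 0.45),
        EffectSpec("sugar_soft_drinks", +1, 0.35),
    )
    latent_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_individuals": self.n_individuals,
            "n_known_t2d": self.n_known_t2d,
            "n_new_diagnosis": self.n_new_diagnosis,
            "n_followup": self.n_followup,
            "n_followup_eligible": self.n_followup_eligible,
            "n_incident": self.n_incident,
            "n_municipalities": self.n_municipalities,
            "n_covered_municipalities": self.n_covered_municipalities,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {value}")
        if self.n_individuals <= 0 or self.n_municipalities <= 0:
            raise ConfigurationError("cohort and municipality counts must be positive")
        if self.n_known_t2d + self.n_new_diagnosis > self.n_individuals:
            raise ConfigurationError("known + new-diagnosis T2D exceeds cohort size")
        if not (self.n_followup_eligible <= self.n_followup <= self.n_individuals):
            raise ConfigurationError(
                "need n_followup_eligible <= n_followup <= n_individuals")
        if self.n_incident > self.n_followup_eligible:
            raise ConfigurationError("incident count exceeds follow-up-eligible count")
        if self.n_covered_municipalities > self.n_municipalities:
            raise ConfigurationError("covered municipalities exceed total municipalities")
        extra = (self.n_followup - self.n_followup_eligible
                 - self.n_followup_known_t2d - self.n_followup_baseline_cases)
        if extra < 0:
            raise ConfigurationError("follow-up composition exceeds n_followup")
        if self.n_followup_known_t2d > self.n_known_t2d:
            raise ConfigurationError("more known-T2D follow-up members than known-T2D")
        if self.n_followup_baseline_cases > self.n_new_diagnosis:
            raise ConfigurationError("more baseline-case follow-up members than cases")

    @property
    def n_followup_incomplete(self) -> int:
        return (self.n_followup - self.n_followup_eligible
                - self.n_followup_known_t2d - self.n_followup_baseline_cases)

    @staticmethod
    def smoke(seed: int = 0) -> "CohortConfig":
        """Small configuration for fast end-to-end runs."""
        return CohortConfig(
            n_individuals=300, n_known_t2d=30, n_new_diagnosis=16,
            n_followup=150, n_followup_eligible=120, n_incident=12,
            n_followup_known_t2d=15, n_followup_baseline_cases=8,
            n_municipalities=30, n_covered_municipalities=12, n_regions=5,
            n_pollution_metrics=3,
            feature_inventory=FeatureInventory(
                ffq_group_sources={
                    "tea_and_infusions": 2, "coffee": 2, "caffeinated_extra": 2,
                    "wine": 2, "alcohol_extra": 2, "vegetables_legumes": 3,
                    "fried_precooked": 2, "eggs_dairy": 2, "carbohydrate_rich": 4,
                    "sugar_snacks_desserts": 3, "fatty_sides": 2,
                },
                n_wholegrain_sources=2,
                n_lifestyle_singles=len(NAMED_SINGLES),
            ),
            seed=seed,
        )


@dataclass
class CohortBundle:
    """In-memory cohort: values, observed mask, per-feature metadata,
    municipality links, labels and the municipality table itself.

    Invariants: mask is True exactly where a value is present; every
    individual has a municipality_id; incident_t2d implies in_followup,
    followup_complete, and neither known_t2d nor baseline_new_diagnosis.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    metadata: pd.DataFrame
    municipality_id: pd.Series
    labels: pd.DataFrame
    municipalities: pd.DataFrame

    def copy(self) -> "CohortBundle":
        return CohortBundle(
            values=self.values.copy(), mask=self.mask.copy(),
            metadata=self.metadata.copy(),
            municipality_id=self.municipality_id.copy(),
            labels=self.labels.copy(),
            municipalities=self.municipalities.copy(),
        )

    @property
    def n_individuals(self) -> int:
        return len(self.values)

    def feature_names(self, domain: str | None = None) -> list[str]:
        meta = self.metadata
        if domain is not None:
            meta = meta[meta["domain"] == domain]
        return [c for c in self.values.columns if c in set(meta.index)]

    def save(self, out_dir: str | Path) -> None:
        """Write the cohort as delimited text plus a JSON metadata sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.values.where(self.mask).to_csv(out / "cohort.csv", index_label="individual")
        self.labels.to_csv(out / "labels.csv", index_label="individual")
        self.municipality_id.rename("municipality_id").to_csv(
            out / "municipality_links.csv", index_label="individual")
        self.municipalities.to_csv(out / "municipalities.csv", index=False)
        sidecar = {
            "features": {
                name: {k: (None if pd.isna(v) else v) for k, v in row.items()}
                for name, row in self.metadata.iterrows()
            }
        }
        (out / "metadata.json").write_text(
            json.dumps(sidecar, indent=1,
                       default=lambda o: o.item() if hasattr(o, "item") else str(o)))


def _stable_key(stream: str) -> int:
    """Process-independent 31-bit key for a named random stream."""
    digest = hashlib.sha256(stream.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _rng_for(config: CohortConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible per-stage stream derived from the config seed."""
    child = np.random.SeedSequence(config.seed, spawn_key=(_stable_key(stream),))
    return np.random.default_rng(child)


def generate_municipality_table(config: CohortConfig) -> pd.DataFrame:
    """Synthetic municipality registry on an abstract bounded planar square.

    Columns: municipality_id, canonical_name, x, y, population, income
    (missing for a configurable fraction), covered (pollution registry
    exists), region_id, and for covered rows one list-valued column per
    pollution metric holding the yearly series (oldest -> newest).
    """
    n, n_cov = config.n_municipalities, config.n_covered_municipalities
    rng = _rng_for(config, "municipalities")
    ids = [f"M{i:04d}" for i in range(n)]
    names = [f"municipio {i:04d}" for i in range(n)]
    coords = rng.uniform(0.0, 100.0, size=(n, 2))
    population = np.round(np.exp(rng.normal(8.5, 1.4, size=n))).astype(int) + 100
    income = np.round(rng.normal(15000.0, 3500.0, size=n), 1)
    n_income_missing = int(round(config.income_missing_fraction * n))
    income_missing_idx = rng.choice(n, size=n_income_missing, replace=False)
    income = income.astype(float)
    income[income_missing_idx] = np.nan
    covered = np.zeros(n, dtype=bool)
    covered[rng.choice(n, size=n_cov, replace=False)] = True

    # contiguous strips along x -> spatially coherent regions
    order = np.argsort(coords[:, 0], kind="stable")
    region = np.empty(n, dtype=int)
    for r, chunk in enumerate(np.array_split(order, config.n_regions)):
        region[chunk] = r

    table = pd.DataFrame({
        "municipality_id": ids,
        "canonical_name": names,
        "x": coords[:, 0],
        "y": coords[:, 1],
        "population": population,
        "income": income,
        "covered": covered,
        "region_id": [f"R{r:02d}" for r in region],
    })
    metrics = POLLUTION_METRIC_NAMES[: config.n_pollution_metrics]
    base = {
        m: rng.uniform(5.0, 60.0, size=n) for m in metrics
    }
    for m in metrics:
        series_col = []
        for i in range(n):
            if covered[i]:
                trend = rng.normal(0.0, 0.3) * np.arange(config.n_pollution_years)
                noise = rng.normal(0.0, base[m][i] * 0.05, size=config.n_pollution_years)
                series = np.maximum(base[m][i] + trend + noise, 0.01)
                series_col.append(list(np.round(series, 4)))
            else:
                series_col.append(None)
        table[f"pollution_{m}"] = series_col
    return table


def _build_metadata(config: CohortConfig) -> pd.DataFrame:
    """Per-feature metadata for the raw (pre-engineering) layer plus the
    geospatial placeholders populated by the generator."""
    inv = config.feature_inventory
    rows = []

    def add(name, domain, source, period=None, derived_from=None, group=None,
            block=None, wholegrain=False, nominal_hint=False):
        rows.append(dict(name=name, domain=domain, source=source,
                         declared_period=period, derived_from=derived_from,
                         group=group, block=block, whole_grain=wholegrain,
                         nominal_hint=nominal_hint))

    # anthropometrics / age / sex (+ threshold-derived flags to be dropped)
    for name in ["age", "height_cm", "weight_kg", "bmi", "waist_cm", "hip_cm"]:
        add(name, "ENV", "anthropometric")
    add("sex", "ENV", "anthropometric", nominal_hint=True)
    add("obesity_bmi_ge_30", "ENV", "anthropometric", derived_from="bmi",
        nominal_hint=True)
    add("underweight_bmi_le_19", "ENV", "anthropometric", derived_from="bmi",
        nominal_hint=True)
    add("high_waist_flag", "ENV", "anthropometric", derived_from="waist_cm",
        nominal_hint=True)

    # diseases and treatments
    disease_flags = [
        "hypertension", "dyslipidemia", "statin_treatment",
        "cardiovascular_disease", "gestational_diabetes_history",
        "thyroid_disease", "corticosteroid_treatment", "diuretic_treatment",
        "chronic_kidney_disease", "depression_treatment",
    ]
    for name in disease_flags:
        add(name, "ENV", "disease", nominal_hint=True)
    add("n_hypotensive_drugs", "ENV", "disease")
    add("polypharmacy_flag", "ENV", "disease", derived_from="n_hypotensive_drugs",
        nominal_hint=True)

    # smoking sub-questions
    add("current_smoker", "ENV", "lifestyle", nominal_hint=True)
    add("years_smoked", "ENV", "lifestyle", group="smoking")
    add("cigarettes_per_day", "ENV", "lifestyle", group="smoking")

    # individual lifestyle items
    singles = list(NAMED_SINGLES)
    periods = ["day", "week", "month"]
    i = 0
    while len(singles) < inv.n_lifestyle_singles:
        singles.append((f"lifestyle_item_{i:02d}", periods[i % 3]))
        i += 1
    singles = singles[: inv.n_lifestyle_singles]
    for name, period in singles:
        block = "exercise" if "met_minutes" in name or name == "physical_activity_workdays" else None
        if block is None and period is not None:
            block = "ffq"
        add(name, "ENV", "lifestyle", period=period, block=block)

    # grouped food-frequency sources
    for group, count in inv.ffq_group_sources.items():
        for j in range(count):
            period = periods[j % 3]
            wholegrain = (group == "carbohydrate_rich" and j < inv.n_wholegrain_sources)
            add(f"{group}_item_{j:02d}", "ENV", "lifestyle", period=period,
                group=group, block="ffq", wholegrain=wholegrain)

    # geospatial placeholders (filled by the generator, finalized by augmentation)
    add("population", "ENV", "geospatial")
    add("income", "ENV", "geospatial")
    for m in POLLUTION_METRIC_NAMES[: config.n_pollution_metrics]:
        add(f"pollution_{m}", "ENV", "geospatial")

    for name in CLINICAL_FEATURES:
        add(name, "CLI", "clinical")

    meta = pd.DataFrame(rows).set_index("name")
    if meta.index.duplicated().any():
        raise ConfigurationError("duplicate feature names in inventory")
    return meta


def _draw_features(config: CohortConfig, meta: pd.DataFrame,
                   muni_table: pd.DataFrame,
                   municipality_id: pd.Series) -> pd.DataFrame:
    from .geospatial import weighted_moving_average  # local import: avoids cycle

    n = config.n_individuals
    rng = _rng_for(config, "features")
    values: dict = {}

    age = np.clip(rng.normal(49.0, 16.0, n), 18, 90).round(0)
    sexv = rng.integers(0, 2, n).astype(float)
    height = rng.normal(163.2, 9.4, n).round(1)
    bmi = np.clip(rng.normal(27.8, 5.1, n), 16, 55).round(2)
    weight = (bmi * (height / 100.0) ** 2).round(1)
    waist = np.clip(92.8 + 2.2 * (bmi - 27.8) + rng.normal(0, 4.0, n), 50, None).round(1)
    hip = np.clip(104.4 + 1.5 * (bmi - 27.8) + rng.normal(0, 4.0, n), 60, None).round(1)
    values["age"] = age
    values["height_cm"] = height
    values["weight_kg"] = weight
    values["bmi"] = bmi
    values["waist_cm"] = waist
    values["hip_cm"] = hip
    values["sex"] = sexv
    values["obesity_bmi_ge_30"] = (bmi >= 30).astype(float)
    values["underweight_bmi_le_19"] = (bmi <= 19).astype(float)
    values["high_waist_flag"] = (waist > 102).astype(float)

    flag_probs = {
        "hypertension": 0.30, "dyslipidemia": 0.25, "statin_treatment": 0.15,
        "cardiovascular_disease": 0.06, "gestational_diabetes_history": 0.03,
        "thyroid_disease": 0.08, "corticosteroid_treatment": 0.03,
        "diuretic_treatment": 0.08, "chronic_kidney_disease": 0.03,
        "depression_treatment": 0.10,
    }
    for name, p in flag_probs.items():
        values[name] = (rng.random(n) < p).astype(float)
    n_drugs = rng.poisson(0.3, n).astype(float)
    values["n_hypotensive_drugs"] = n_drugs
    values["polypharmacy_flag"] = (n_drugs >= 2).astype(float)

    ever_smoked = rng.random(n) < 0.45
    current = ever_smoked & (rng.random(n) < 0.55)
    values["current_smoker"] = current.astype(float)
    values["years_smoked"] = np.where(
        ever_smoked, rng.uniform(1, 40, n).round(0), 0.0)
    values["cigarettes_per_day"] = np.where(
        ever_smoked, rng.poisson(12, n).astype(float), 0.0)

    period_factor = {"day": 1 / 30.0, "week": 7 / 30.0, "month": 1.0, None: 1.0}
    monthly_scale = {"exercise": None}
    for name, row in meta.iterrows():
        if name in values or row["source"] == "geospatial" or row["domain"] == "CLI":
            continue
        if row["block"] == "exercise" or "met_minutes" in str(name):
            continue
        # FFQ-style count with a per-item monthly base rate, reported in the
        # item's declared period
        lam_month = rng.uniform(1.0, 25.0)
        lam = lam_month * period_factor[row["declared_period"]]
        values[name] = rng.poisson(lam, n).astype(float)

    values["physical_activity_workdays"] = rng.integers(1, 4, n).astype(float)
    values["hours_of_sleep"] = np.clip(rng.normal(7.3, 1.3, n), 3, 12).round(1)
    values["walking_met_minutes_week"] = np.round(rng.exponential(1348.0, n), 0)
    values["moderate_met_minutes_week"] = np.round(rng.exponential(559.0, n), 0)
    values["vigorous_met_minutes_week"] = np.round(rng.exponential(250.0, n), 0)
    values["t2d_relatives_first_degree"] = rng.poisson(0.4, n).astype(float)
    values["t2d_relatives_second_degree"] = rng.poisson(0.6, n).astype(float)

    clin_params = {
        "fasting_glucose": (94.0, 19.5), "hba1c": (5.5, 0.6),
        "triglycerides": (117.2, 84.5), "total_cholesterol": (200.0, 38.0),
        "hdl_cholesterol": (52.8, 12.9), "ldl_cholesterol": (120.0, 32.0),
        "aspartate_transaminase": (0.3, 0.2), "alanine_transaminase": (0.35, 0.25),
        "gamma_glutamyl_transferase": (0.5, 0.6), "fasting_insulin": (9.0, 6.0),
        "creatinine": (0.9, 0.2), "uric_acid": (5.2, 1.4),
        "c_reactive_protein": (2.5, 3.0), "tsh": (2.2, 1.2),
        "ferritin": (90.0, 70.0), "albumin": (4.4, 0.3),
    }
    for name, (mu, sd) in clin_params.items():
        values[name] = np.maximum(rng.normal(mu, sd, n), 0.01).round(3)

    # geospatial layer: own-municipality truth (augmentation later re-derives
    # and fills the uncovered holes)
    muni = muni_table.set_index("municipality_id")
    values["population"] = muni["population"].reindex(municipality_id).to_numpy(dtype=float)
    values["income"] = muni["income"].reindex(municipality_id).to_numpy(dtype=float)
    metrics = POLLUTION_METRIC_NAMES[: config.n_pollution_metrics]
    aggregates = {}
    for m in metrics:
        agg = {}
        for mid, series in muni[f"pollution_{m}"].items():
            agg[mid] = weighted_moving_average(series) if series is not None else np.nan
        aggregates[m] = agg
    for m in metrics:
        values[f"pollution_{m}"] = municipality_id.map(aggregates[m]).to_numpy(dtype=float)

    # column order follows metadata
    frame = pd.DataFrame(values, index=pd.RangeIndex(n))
    return frame[[c for c in meta.index]]


def generate_cohort(config: CohortConfig,
                    municipality_table: pd.DataFrame | None = None) -> CohortBundle:
    """Generate a complete (pre-missingness) cohort bundle.

    The raw feature layer includes redundant threshold-derived flags,
    per-item food-frequency counts in mixed declared periods, smoking
    sub-questions, anthropometrics, disease/treatment flags and clinical
    biochemistry. Labels are assigned by exact-count thresholding of a
    latent linear risk score over ``config.effect_spec``.
    """
    muni_table = (municipality_table if municipality_table is not None
                  else generate_municipality_table(config))
    meta = _build_metadata(config)
    for eff in config.effect_spec:
        if eff.feature not in meta.index:
            raise ConfigurationError(
                f"effect_spec names unknown feature {eff.feature!r}")

    n = config.n_individuals
    rng_geo = _rng_for(config, "municipality-assignment")
    n_uncov_res = int(round(config.uncovered_resident_fraction * n))
    covered_ids = muni_table.loc[muni_table["covered"], "municipality_id"].to_numpy()
    uncovered_ids = muni_table.loc[~muni_table["covered"], "municipality_id"].to_numpy()
    if len(uncovered_ids) == 0:
        n_uncov_res = 0
    if len(covered_ids) == 0:
        n_uncov_res = n
    assignment = np.empty(n, dtype=object)
    uncov_res = rng_geo.choice(n, size=n_uncov_res, replace=False)
    is_uncov = np.zeros(n, dtype=bool)
    is_uncov[uncov_res] = True
    if n_uncov_res:
        assignment[is_uncov] = rng_geo.choice(uncovered_ids, size=n_uncov_res)
    if n - n_uncov_res:
        assignment[~is_uncov] = rng_geo.choice(covered_ids, size=n - n_uncov_res)
    municipality_id = pd.Series(assignment, index=pd.RangeIndex(n), name="municipality_id")

    values = _draw_features(config, meta, muni_table, municipality_id)

    # latent linear risk on log-odds scale over standardized drivers
    rng_lab = _rng_for(config, "labels")
    latent = rng_lab.normal(0.0, config.latent_noise_sd, n)
    for eff in config.effect_spec:
        x = values[eff.feature].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        latent = latent + eff.direction * eff.magnitude * z
    # seed-stable tie break
    tiebreak = rng_lab.permutation(n)
    order = np.lexsort((tiebreak, -latent))  # descending latent

    labels = pd.DataFrame(False, index=pd.RangeIndex(n), columns=[
        "known_t2d", "baseline_new_diagnosis", "in_followup",
        "followup_complete", "incident_t2d"])
    known_idx = order[: config.n_known_t2d]
    labels.loc[known_idx, "known_t2d"] = True
    remaining = order[config.n_known_t2d:]
    new_idx = remaining[: config.n_new_diagnosis]
    labels.loc[new_idx, "baseline_new_diagnosis"] = True
    pool = remaining[config.n_new_diagnosis:]  # latent-descending order

    rng_fu = _rng_for(config, "followup")
    eligible = rng_fu.choice(pool, size=config.n_followup_eligible, replace=False)
    eligible_set = set(eligible.tolist())
    # incident = top-latent among the eligible (pool is already ordered)
    incident = [i for i in pool if i in eligible_set][: config.n_incident]
    labels.loc[list(eligible), ["in_followup", "followup_complete"]] = True
    labels.loc[incident, "incident_t2d"] = True

    fu_known = rng_fu.choice(known_idx, size=config.n_followup_known_t2d,
                             replace=False) if config.n_followup_known_t2d else []
    fu_cases = rng_fu.choice(new_idx, size=config.n_followup_baseline_cases,
                             replace=False) if config.n_followup_baseline_cases else []
    non_eligible_pool = np.array([i for i in pool if i not in eligible_set])
    fu_incomplete = (rng_fu.choice(non_eligible_pool, size=config.n_followup_incomplete,
                                   replace=False)
                     if config.n_followup_incomplete else [])
    for idx in (fu_known, fu_cases):
        labels.loc[list(idx), ["in_followup", "followup_complete"]] = True
    labels.loc[list(fu_incomplete), "in_followup"] = True

    fu_years = np.full(n, np.nan)
    in_fu = labels["in_followup"].to_numpy()
    fu_years[in_fu] = rng_fu.normal(config.followup_years_mean,
                                    config.followup_years_sd, in_fu.sum()).round(2)
    labels["followup_years"] = fu_years

    mask = pd.DataFrame(True, index=values.index, columns=values.columns)
    # pre-missingness: only structurally absent values are masked out
    mask[values.isna()] = False

    return CohortBundle(values=values, mask=mask, metadata=meta,
                        municipality_id=municipality_id, labels=labels,
                        municipalities=muni_table)


def inject_missingness(cohort: CohortBundle, config: CohortConfig) -> CohortBundle:
    """Apply the three missingness mechanisms and return a new bundle.

    (a) feature-wise MCAR at per-source rates, (b) block-monotone wipes
    driven by an individual-level indicator (food-frequency questionnaire,
    exercise items), (c) geospatial holes that are a deterministic function
    of municipality coverage (pollution) and municipal income availability.
    """
    spec = config.missingness_spec
    for rate in list(spec.mcar_rates.values()) + list(spec.block_rates.values()):
        if not (0.0 <= rate <= 1.0):
            raise ConfigurationError(f"missingness rate {rate} outside [0, 1]")
    out = cohort.copy()
    meta = out.metadata
    n = out.n_individuals
    rng = _rng_for(config, "missingness")

    for source, rate in spec.mcar_rates.items():
        cols = meta.index[(meta["source"] == source)]
        for col in cols:
            if col not in out.values.columns:
                raise ConfigurationError(f"MCAR spec references unknown feature {col}")
            hit = rng.random(n) < rate
            out.mask.loc[hit, col] = False

    for block, rate in spec.block_rates.items():
        cols = list(meta.index[meta["block"] == block])
        if not cols:
            raise ConfigurationError(f"block {block!r} references no known features")
        wiped = rng.random(n) < rate
        out.mask.loc[wiped, cols] = False

    muni = out.municipalities.set_index("municipality_id")
    covered = muni["covered"].reindex(out.municipality_id).to_numpy()
    income_known = muni["income"].notna().reindex(out.municipality_id).to_numpy()
    pollution_cols = [c for c in out.values.columns if c.startswith("pollution_")]
    out.mask.loc[~covered, pollution_cols] = False
    out.mask.loc[~income_known, "income"] = False

    out.values = out.values.where(out.mask)
    return out
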
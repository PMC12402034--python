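"""Feature engineering: collapse raw questionnaire items into semantic
groups and remove redundant threshold-derived variables.

The raw layer of a questionnaire-heavy cohort carries (i) food-frequency
items reported in mixed declared periods (per day / week / month), (ii)
smoking sub-questions, (iii) threshold flags that are deterministic
functions of a continuous parent (e.g. an obesity flag derived from BMI).
Engineering standardizes frequencies to a canonical period, sums items of
one semantic group into a representative feature (removing the sources),
derives smoking pack-years and the waist-to-hip ratio, and drops every
threshold-derived flag while keeping the parent.

Conventions (documented, configurable):

* canonical frequency period is MONTH with conversion factors 30 days per
  month and 7 days per week;
* a group value is missing iff *all* of its sources are missing; otherwise
  missing sources contribute 0, so questionnaire block-missingness
  propagates to groups without silently shrinking the sums;
* pack size is 20 cigarettes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "EngineeringConfig",
    "GroupingMap",
    "GroupRule",
    "normalize_frequency",
    "smoking_pack_years",
    "aggregate_groups",
    "drop_derived_thresholds",
    "waist_hip_ratio",
    "default_grouping_map",
    "engineer_features",
]

PERIOD_DAYS = {"day": 1.0, "week": 7.0, "month": 30.0}


@dataclass(frozen=True)
class EngineeringConfig:
    canonical_period: str = "month"
    pack_size: int = 20


@dataclass(frozen=True)
class GroupRule:
    """One engineered group.

    mode 'sum': output = Σ normalized sources (+ previously computed
    ``include_groups`` outputs, enabling nested semantics such as
    caffeinated ⊇ coffee without any source feeding two sum-groups).
    mode 'fraction': output = Σ numerator sources / Σ all sources, in [0,1];
    fraction groups do not remove their sources (a sibling sum-group does).
    """

    name: str
    mode: str  # 'sum' | 'fraction'
    sources: tuple
    numerator: tuple = ()
    include_groups: tuple = ()


@dataclass
class GroupingMap:
    rules: list = field(default_factory=list)

    def validate(self, columns) -> None:
        colset = set(columns)
        claimed: dict[str, str] = {}
        for rule in self.rules:
            if not rule.sources and not rule.include_groups:
                raise ConfigurationError(f"group {rule.name!r} is empty")
            for src in rule.sources:
                if src not in colset:
                    raise ConfigurationError(
                        f"group {rule.name!r} references unknown feature {src!r}")
                if rule.mode == "sum":
                    if src in claimed:
                        raise ConfigurationError(
                            f"feature {src!r} claimed by sum-groups "
                            f"{claimed[src]!r} and {rule.name!r}")
                    claimed[src] = rule.name


def normalize_frequency(value: float, declared_period: str,
                        config: EngineeringConfig = EngineeringConfig()) -> float:
    """Convert a count per declared period to a count per canonical period."""
    if declared_period not in PERIOD_DAYS:
        raise DataError(f"unknown declared period {declared_period!r}")
    if value < 0:
        raise DataError(f"frequency count must be >= 0, got {value}")
    factor = PERIOD_DAYS[config.canonical_period] / PERIOD_DAYS[declared_period]
    return value * factor


def smoking_pack_years(years_smoked: float, cigarettes_per_day: float,
                       config: EngineeringConfig = EngineeringConfig()) -> float:
    """years smoked x packs per day (pack = 20 cigarettes)."""
    if years_smoked < 0 or cigarettes_per_day < 0:
        raise DataError("smoking inputs must be >= 0")
    return years_smoked * (cigarettes_per_day / config.pack_size)


def waist_hip_ratio(waist: float, hip: float) -> float:
    """Waist circumference divided by hip circumference (dimensionless)."""
    if np.isnan(waist) or np.isnan(hip):
        return float("nan")
    if hip <= 0:
        raise DataError(f"hip circumference must be > 0, got {hip}")
    return waist / hip


def default_grouping_map(metadata: pd.DataFrame) -> GroupingMap:
    """Build the shipped semantic grouping from metadata 'group' tags."""
    def members(tag):
        return tuple(metadata.index[metadata["group"] == tag])

    carbs = members("carbohydrate_rich")
    wholegrain = tuple(metadata.index[
        (metadata["group"] == "carbohydrate_rich")
        & metadata["whole_grain"].fillna(False).astype(bool)])
    rules = [
        GroupRule("tea_and_infusions_per_month", "sum", members("tea_and_infusions")),
        GroupRule("coffee_intake_per_month", "sum", members("coffee")),
        GroupRule("caffeinated_beverages_per_month", "sum",
                  members("caffeinated_extra"),
                  include_groups=("coffee_intake_per_month",)),
        GroupRule("wine_consumption_per_month", "sum", members("wine")),
        GroupRule("alcohol_consumption_per_month", "sum", members("alcohol_extra"),
                  include_groups=("wine_consumption_per_month",)),
        GroupRule("vegetables_legumes_intake_per_month", "sum",
                  members("vegetables_legumes")),
        GroupRule("fried_precooked_intake_per_month", "sum",
                  members("fried_precooked")),
        GroupRule("eggs_dairy_intake_per_month", "sum", members("eggs_dairy")),
        GroupRule("whole_grain_fraction", "fraction", carbs, numerator=wholegrain),
        GroupRule("carbohydrate_rich_intake_per_month", "sum", carbs),
        GroupRule("sugar_snacks_desserts_per_month", "sum",
                  members("sugar_snacks_desserts")),
        GroupRule("fatty_sides_intake_per_month", "sum", members("fatty_sides")),
    ]
    return GroupingMap([r for r in rules if r.sources or r.include_groups])


def _normalize_all_frequencies(bundle, config: EngineeringConfig):
    """Vectorized period standardization over all declared-period columns."""
    meta = bundle.metadata
    for col in meta.index[meta["declared_period"].notna()]:
        period = meta.loc[col, "declared_period"]
        if period == config.canonical_period:
            continue
        factor = PERIOD_DAYS[config.canonical_period] / PERIOD_DAYS[period]
        bundle.values[col] = bundle.values[col] * factor
        bundle.metadata.loc[col, "declared_period"] = config.canonical_period


def aggregate_groups(bundle, grouping: GroupingMap,
                     config: EngineeringConfig = EngineeringConfig()):
    """Apply sum/fraction group rules; returns a new bundle.

    Sources consumed by sum-groups are removed from values, mask and
    metadata; engineered outputs inherit domain ENV / source lifestyle and
    the union block tag of their sources.
    """
    out = bundle.copy()
    present = [r for r in grouping.rules
               if all(s in out.values.columns for s in r.sources) and r.sources]
    if not present:
        return out
    grouping_present = GroupingMap(present)
    grouping_present.validate(out.values.columns)

    new_cols = {}
    new_mask = {}
    new_meta = {}
    to_remove: set[str] = set()
    for rule in present:
        vals = out.values[list(rule.sources)]
        observed = out.mask[list(rule.sources)]
        any_obs = observed.any(axis=1)
        if rule.mode == "sum":
            total = vals.where(observed).fillna(0.0).sum(axis=1)
            for g in rule.include_groups:
                if g in new_cols:
                    total = total + new_cols[g].where(new_mask[g], 0.0)
                    any_obs = any_obs | new_mask[g]
            new_cols[rule.name] = total.where(any_obs)
            to_remove.update(rule.sources)
        elif rule.mode == "fraction":
            num = (out.values[list(rule.numerator)]
                   .where(out.mask[list(rule.numerator)]).fillna(0.0).sum(axis=1))
            den = vals.where(observed).fillna(0.0).sum(axis=1)
            frac = np.where(den > 0, num / den, 0.0)
            new_cols[rule.name] = pd.Series(frac, index=out.values.index).where(any_obs)
        else:
            raise ConfigurationError(f"unknown aggregation mode {rule.mode!r}")
        new_mask[rule.name] = any_obs
        blocks = set(out.metadata.loc[list(rule.sources), "block"].dropna())
        new_meta[rule.name] = dict(
            domain="ENV", source="lifestyle",
            declared_period=(config.canonical_period if rule.mode == "sum" else None),
            derived_from=None, group=None,
            block=(blocks.pop() if len(blocks) == 1 else None),
            whole_grain=False, nominal_hint=False)

    keep = [c for c in out.values.columns if c not in to_remove]
    out.values = pd.concat([out.values[keep], pd.DataFrame(new_cols)], axis=1)
    out.mask = pd.concat([out.mask[keep], pd.DataFrame(new_mask)], axis=1)
    out.metadata = pd.concat([
        out.metadata.loc[[c for c in out.metadata.index if c not in to_remove]],
        pd.DataFrame(new_meta).T.rename_axis("name"),
    ])
    return out


def drop_derived_thresholds(bundle):
    """Remove every feature tagged as threshold-derived, keeping parents."""
    out = bundle.copy()
    derived = list(out.metadata.index[out.metadata["derived_from"].notna()])
    derived = [c for c in derived if c in out.values.columns]
    if derived:
        out.values = out.values.drop(columns=derived)
        out.mask = out.mask.drop(columns=derived)
        out.metadata = out.metadata.drop(index=derived)
    return out


def engineer_features(bundle, grouping: GroupingMap | None = None,
                      config: EngineeringConfig = EngineeringConfig()):
    """Full engineering stage; idempotent on an already-engineered bundle.

    Order: frequency standardization -> smoking pack-years -> semantic
    group aggregation -> waist-to-hip ratio -> threshold-derived removal.
    Row count is never altered.
    """
    out = bundle.copy()
    _normalize_all_frequencies(out, config)

    if {"years_smoked", "cigarettes_per_day"} <= set(out.values.columns):
        years = out.values["years_smoked"]
        cigs = out.values["cigarettes_per_day"]
        packs = years * (cigs / config.pack_size)
        ok = out.mask["years_smoked"] & out.mask["cigarettes_per_day"]
        out.values = out.values.assign(smoking_pack_years=packs.where(ok))
        out.mask = out.mask.assign(smoking_pack_years=ok)
        out.metadata.loc["smoking_pack_years"] = dict(
            domain="ENV", source="lifestyle", declared_period=None,
            derived_from=None, group=None, block=None, whole_grain=False,
            nominal_hint=False)
        out.values = out.values.drop(columns=["years_smoked", "cigarettes_per_day"])
        out.mask = out.mask.drop(columns=["years_smoked", "cigarettes_per_day"])
        out.metadata = out.metadata.drop(index=["years_smoked", "cigarettes_per_day"])

    grouping = grouping if grouping is not None else default_grouping_map(out.metadata)
    out = aggregate_groups(out, grouping, config)

    if ({"waist_cm", "hip_cm"} <= set(out.values.columns)
            and "waist_hip_ratio" not in out.values.columns):
        ok = out.mask["waist_cm"] & out.mask["hip_cm"]
        ratio = out.values["waist_cm"] / out.values["hip_cm"]
        out.values["waist_hip_ratio"] = ratio.where(ok)
        out.mask["waist_hip_ratio"] = ok
        out.metadata.loc["waist_hip_ratio"] = dict(
            domain="ENV", source="anthropometric", declared_period=None,
            derived_from=None, group=None, block=None, whole_grain=False,
            nominal_hint=False)

    out = drop_derived_thresholds(out)
    return out
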
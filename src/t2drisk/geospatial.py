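"""Geospatial augmentation of a cohort.

Pollution series are first collapsed over time with a weighted moving
average that up-weights recent years,

    x̄_w = Σ_{i=1..n} i·x_i / w,   w = n(n+1)/2   (oldest -> newest),

then municipalities without a pollution registry receive the
inverse-distance-weighted (IDW) average of the k nearest covered
municipalities' aggregates,

    f̂_m = Σ_i w_i f_i / Σ_j w_j,   w_l = 1 / d(m, l)^β,

with Euclidean distance d, elasticity exponent β (default 2.0, which
quadratically penalizes distance) and k = 10 neighbours. Temporal
aggregation is applied *before* spatial imputation, so the IDW step
operates on one scalar per metric per municipality; the two orders are
equivalent under linearity of both operators.

Region labels (municipalities grouped into spatially coherent regions)
are the unit of every later train/test split, so that a model cannot
exploit region-specific geospatial anomalies across a split boundary.
"""

from __future__ import annotations

import unicodedata

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, InputError

__all__ = [
    "IDWConfig",
    "weighted_moving_average",
    "idw_impute",
    "augment_cohort_geospatial",
    "region_groups",
    "standardize_municipality_name",
]


class IDWConfig:
    """Inverse-distance weighting parameters: exponent beta > 0 and
    neighbour count k >= 1."""

    def __init__(self, beta: float = 2.0, k: int = 10):
        if beta <= 0:
            raise ConfigurationError(f"beta must be > 0, got {beta}")
        if k < 1:
            raise ConfigurationError(f"k must be >= 1, got {k}")
        self.beta = float(beta)
        self.k = int(k)

    def __repr__(self) -> str:  # pragma: no cover
        return f"IDWConfig(beta={self.beta}, k={self.k})"


def weighted_moving_average(series) -> float:
    """Recency-weighted mean of a yearly series (oldest -> newest)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise InputError("series must be a non-empty 1-D vector")
    if np.isnan(x).any():
        raise InputError("series must not contain missing entries")
    n = x.size
    i = np.arange(1, n + 1)
    w = n * (n + 1) / 2.0
    return float(np.sum(i * x) / w)


def idw_impute(query, neighbors, cfg: IDWConfig | None = None) -> float:
    """IDW estimate at ``query`` from ``neighbors`` = [(coords, value), ...].

    Selects the k nearest neighbours by Euclidean distance (all if fewer),
    weights them by 1/d^beta and returns the weighted average. An exact
    coordinate match short-circuits to that neighbour's value.
    """
    cfg = cfg or IDWConfig()
    if not neighbors:
        raise InputError("idw_impute needs at least one neighbor")
    q = np.asarray(query, dtype=float)
    coords = np.asarray([np.asarray(c, dtype=float) for c, _ in neighbors])
    vals = np.asarray([v for _, v in neighbors], dtype=float)
    if np.isnan(vals).any():
        raise InputError("neighbor values must be finite")
    d = np.linalg.norm(coords - q, axis=1)
    zero = d == 0.0
    if zero.any():
        return float(vals[np.argmax(zero)])
    k = min(cfg.k, len(vals))
    nearest = np.argsort(d, kind="stable")[:k]
    w = 1.0 / d[nearest] ** cfg.beta
    return float(np.sum(w * vals[nearest]) / np.sum(w))


def augment_cohort_geospatial(cohort, table: pd.DataFrame | None = None,
                              cfg: IDWConfig | None = None):
    """Return a new bundle whose geospatial block (population, income and
    one aggregated column per pollution metric) is complete for every
    individual. Covered municipalities contribute their own aggregates;
    uncovered ones are filled by IDW over the covered pool only.
    Non-geospatial columns are never altered.
    """
    cfg = cfg or IDWConfig()
    table = table if table is not None else cohort.municipalities
    known = set(table["municipality_id"])
    unknown = set(cohort.municipality_id) - known
    if unknown:
        raise DataError(f"unknown municipality ids: {sorted(unknown)[:5]}")

    per_muni = _municipality_aggregates_idw(table, cfg)
    out = cohort.copy()
    indexed = per_muni.set_index("municipality_id")
    geo_cols = ["population", "income"] + [
        c for c in per_muni.columns if c.startswith("pollution_")]
    for col in geo_cols:
        out.values[col] = indexed[col].reindex(out.municipality_id).to_numpy()
        out.mask[col] = True
    return out


def _municipality_aggregates_idw(table: pd.DataFrame, cfg: IDWConfig) -> pd.DataFrame:
    """Per-municipality scalar geospatial features: population, income
    (IDW-filled where missing) and the temporal aggregate of each pollution
    metric (own value if covered, IDW over covered aggregates otherwise)."""
    metrics = [c.removeprefix("pollution_") for c in table.columns
               if c.startswith("pollution_")]
    out = table[["municipality_id", "x", "y", "covered", "region_id"]].copy()
    out["population"] = table["population"].astype(float).to_numpy()

    coords = table[["x", "y"]].to_numpy(dtype=float)
    income = table["income"].to_numpy(dtype=float)
    have_income = ~np.isnan(income)
    income_pool = [(coords[i], income[i]) for i in np.flatnonzero(have_income)]
    filled_income = income.copy()
    for i in np.flatnonzero(~have_income):
        filled_income[i] = idw_impute(coords[i], income_pool, cfg)
    out["income"] = filled_income

    covered = table["covered"].to_numpy(dtype=bool)
    for m in metrics:
        agg = np.full(len(table), np.nan)
        for i in np.flatnonzero(covered):
            agg[i] = weighted_moving_average(table[f"pollution_{m}"].iloc[i])
        pool = [(coords[i], agg[i]) for i in np.flatnonzero(covered)]
        for i in np.flatnonzero(~covered):
            agg[i] = idw_impute(coords[i], pool, cfg)
        out[f"pollution_{m}"] = agg
    return out


def region_groups(cohort, table: pd.DataFrame | None = None) -> pd.Series:
    """Per-individual region label (the grouping unit of all later splits)."""
    table = table if table is not None else cohort.municipalities
    mapping = table.set_index("municipality_id")["region_id"]
    groups = cohort.municipality_id.map(mapping)
    if groups.isna().any():
        raise DataError("municipality link could not be resolved to a region")
    return groups.rename("region")


def standardize_municipality_name(raw: str) -> str:
    """Lowercased, accent-stripped, whitespace-collapsed join key."""
    text = unicodedata.normalize("NFKD", str(raw))
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    return " ".join(text.lower().split())
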
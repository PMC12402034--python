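"""Quasi-constancy index: Gini coefficient of an L-transformed feature.

A feature x is first standardized (zero mean, unit variance) and shifted
to the strictly positive domain — the documented convention anchors the
minimum at 1, which bounds the ratios σ/xᵢ and avoids division blow-ups
near zero. The L-transform then maps each observation to s·σ/xᵢ, where σ
is the standard deviation of the shifted vector (= 1 after
standardization) and s = sign(mean − median) of the *original* x flips
negatively skewed distributions into the positive domain (s = +1 when mean
equals median; the formula is 0/0 there, and with σ = 0 the output is zero
regardless, so only symmetric non-constant inputs are affected by the
convention).

The Gini coefficient of |L(x)| — absolute values, since Gini is defined
for nonnegative inputs — serves as a quasi-constancy index in [0, 1]: 0
for a constant feature, increasing with variability and entropy. Features
with an index below the threshold (default 0.05) are filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "QuasiConstancyResult",
    "l_transform",
    "gini",
    "quasi_constancy_index",
    "filter_quasi_constant",
]

DEFAULT_THRESHOLD = 0.05


@dataclass
class QuasiConstancyResult:
    feature: str
    sigma: float
    s: int
    index: float
    retained: bool


def l_transform(x) -> np.ndarray:
    """Map x to (s·σ/x₁, ..., s·σ/xₙ) after standardize-and-shift.

    Constant input returns the all-zeros vector (σ = 0).
    """
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise InputError("l_transform needs a 1-D vector of length >= 2")
    if np.isnan(arr).any():
        raise InputError("l_transform input must be complete")
    sd = arr.std()
    if sd == 0:
        return np.zeros_like(arr)
    z = (arr - arr.mean()) / sd
    shifted = z - z.min() + 1.0  # minimum anchored at 1 (documented convention)
    sigma = shifted.std()
    diff = arr.mean() - np.median(arr)
    s = 1 if diff >= 0 else -1
    return s * sigma / shifted


def gini(values) -> float:
    """Gini coefficient Σᵢⱼ|xᵢ−xⱼ| / (2n²x̄) of a nonnegative vector
    (0 when the mean is 0), computed via the sorted O(n log n) identity."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InputError("gini needs a 1-D vector of length >= 2")
    if (x < 0).any():
        raise InputError("gini is defined for nonnegative values")
    n = x.size
    total = x.sum()
    if total == 0:
        return 0.0
    xs = np.sort(x)
    i = np.arange(1, n + 1)
    return float((2.0 * np.sum(i * xs)) / (n * total) - (n + 1) / n)


def quasi_constancy_index(x) -> float:
    """gini(|l_transform(x)|): tends to 0 for near-constant x."""
    return gini(np.abs(l_transform(x)))


def filter_quasi_constant(table: pd.DataFrame,
                          threshold: float = DEFAULT_THRESHOLD):
    """Retain features whose index is at least ``threshold``.

    Expects a complete (post-imputation) table. Returns (retained feature
    names, list of QuasiConstancyResult diagnostics).
    """
    retained = []
    results = []
    for col in table.columns:
        arr = table[col].to_numpy(dtype=float)
        sd = arr.std()
        diff = arr.mean() - np.median(arr)
        s = 0 if diff == 0 else (1 if diff > 0 else -1)
        idx = quasi_constancy_index(arr)
        keep = idx >= threshold
        results.append(QuasiConstancyResult(col, float(sd), s, idx, keep))
        if keep:
            retained.append(col)
    return retained, results


def results_to_frame(results) -> pd.DataFrame:
    """Diagnostics as a writable table (feature, index, retained)."""
    return pd.DataFrame(
        [dict(feature=r.feature, sigma=r.sigma, s=r.s, index=r.index,
              retained=r.retained) for r in results]
    ).set_index("feature")
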
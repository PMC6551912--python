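"""Comparison and summary utilities for batches of CSM results."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["ComparisonRecord", "relative_error", "batch_stats"]


def relative_error(s_full: float, s_variant: float) -> float:
    """Percent deviation of a variant score from the full (two-level
    Hungarian) score: 100·|full − variant| / full.

    Undefined for a zero full score (a perfectly symmetric structure):
    returns NaN, which batch summaries exclude.
    """
    if s_full < 0 or s_variant < 0:
        raise ValueError("CSM values are non-negative")
    if s_full == 0:
        return math.nan
    return 100.0 * abs(s_full - s_variant) / s_full


@dataclass(frozen=True)
class ComparisonRecord:
    """Full-algorithm score vs. a variant strategy on one structure."""

    source_id: str
    s_full: float
    s_variant: float
    variant: str = "sequence"

    @property
    def relative_error_percent(self) -> float:
        return relative_error(self.s_full, self.s_variant)


def batch_stats(values: list[float] | np.ndarray) -> dict[str, float]:
    """Descriptive statistics (N, mean, sample SD, SE of mean, min,
    median, max) for a batch of CSM values; NaNs are excluded."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("batch_stats needs at least one (finite) value")
    n = int(arr.size)
    sd = float(np.std(arr, ddof=1)) if n > 1 else 0.0
    return {
        "n": n,
        "mean": float(arr.mean()),
        "sd": sd,
        "se_mean": sd / math.sqrt(n),
        "min": float(arr.min()),
        "median": float(np.median(arr)),
        "max": float(arr.max()),
    }
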
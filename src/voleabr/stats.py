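"""Descriptive group summaries, outlier screening, and two-group tests.

Feature tables exported by the analysis stages are summarized the way the
study reports them — mean, standard error, range and N per group — with a
single-pass three-standard-deviation outlier screen and Welch's two-tailed
unequal-variance t-test for simple two-group comparisons. Model-based
inference (mixed models, marginal-means contrasts) is deliberately out of
scope; the tidy feature tables are designed to be handed to external tools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "GroupSummary",
    "summarize",
    "outlier_filter",
    "welch_t",
    "feature_table",
    "summarize_table",
]


@dataclass(frozen=True)
class GroupSummary:
    """mean +/- standard error (range, N) for one group of values."""

    mean: float
    se: float
    min: float
    max: float
    n: int

    def __str__(self):
        return f"{self.mean:.6g} ± {self.se:.6g} ({self.min:.6g}–{self.max:.6g}, {self.n})"


def summarize(values: Sequence[float]) -> GroupSummary:
    """Mean, standard error (sample SD / sqrt(n)), range and N.

    A single value has SE 0 by convention (no spread is estimable).
    """
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty group")
    se = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0
    return GroupSummary(
        mean=float(v.mean()), se=se, min=float(v.min()), max=float(v.max()), n=int(v.size)
    )


def outlier_filter(
    values: Sequence[float], k: float = 3.0
) -> Tuple[List[float], List[float]]:
    """Single-pass k-SD screen: drop values with |v - mean| > k * SD.

    Mean and SD are those of the full input (no re-iteration after removal).
    Zero SD (all values equal) keeps everything.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("outlier screening needs at least two values")
    sd = float(v.std(ddof=1))
    if sd == 0.0 or math.isinf(k):
        return list(map(float, v)), []
    keep = np.abs(v - v.mean()) <= k * sd
    return list(map(float, v[keep])), list(map(float, v[~keep]))


def welch_t(
    a: Sequence[float], b: Sequence[float], two_tailed: bool = True
) -> Tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, df, p).

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with the
    Welch-Satterthwaite degrees of freedom; p is two-tailed by default.
    """
    xa = np.asarray(list(a), dtype=float)
    xb = np.asarray(list(b), dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ValueError("each group needs at least two values")
    va = xa.var(ddof=1) / xa.size
    vb = xb.var(ddof=1) / xb.size
    if va + vb == 0.0:
        raise ValueError("both groups are degenerate (zero variance)")
    t = (xa.mean() - xb.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (xa.size - 1) + vb**2 / (xb.size - 1))
    p = 2.0 * sp_stats.t.sf(abs(t), df)
    if not two_tailed:
        p /= 2.0
    return float(t), float(df), float(p)


def feature_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Tidy feature table: one value per (animal, measure, condition).

    Each row dict must provide ``animal_id``, ``measure``, ``value`` and
    ``units``; any further keys become condition columns. Duplicate
    (animal, measure, condition) combinations are rejected.
    """
    df = pd.DataFrame(list(rows))
    required = {"animal_id", "measure", "value", "units"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"feature rows missing columns: {sorted(missing)}")
    if df["units"].isna().any() or (df["units"] == "").any():
        raise ValueError("units must be non-empty")
    keys = [c for c in df.columns if c != "value"]
    if df.duplicated(subset=keys).any():
        raise ValueError("duplicate (animal, measure, condition) rows")
    return df


def summarize_table(df: pd.DataFrame, by: Sequence[str]) -> pd.DataFrame:
    """Group a feature table and attach mean/SE/range/N per group."""
    def _agg(g):
        s = summarize(g["value"])
        return pd.Series(
            {"mean": s.mean, "se": s.se, "min": s.min, "max": s.max, "n": s.n}
        )

    return df.groupby(list(by)).apply(_agg, include_groups=False).reset_index()
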
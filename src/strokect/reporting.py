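"""Cohort aggregation: summary statistics and method-agreement regression.

Per-sample results from the automatic, manual and TTC workflows are
collected into a long-format table (one row per sample and method) and
summarized as mean +/- SD.  Agreement between two measurement
techniques is assessed by linear regression through the origin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["make_cohort_table", "summarize", "agreement_regression"]

COHORT_COLUMNS = [
    "sample_id",
    "method",
    "total_lesion_mm3",
    "core_mm3",
    "edema_percent",
    "lesion_percent",
]
METHODS = ("automatic", "manual", "ttc")


def make_cohort_table(rows: list[dict]) -> pd.DataFrame:
    """Build a cohort table; one row per (sample, method)."""
    df = pd.DataFrame(rows)
    missing = [c for c in ("sample_id", "method") if c not in df.columns]
    if missing:
        raise ValueError(f"cohort rows must carry {missing}")
    bad = set(df["method"]) - set(METHODS)
    if bad:
        raise ValueError(f"unknown methods: {sorted(bad)}")
    if df.duplicated(subset=["sample_id", "method"]).any():
        raise ValueError("duplicate (sample, method) rows")
    for c in COHORT_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    return df[COHORT_COLUMNS]


def summarize(
    values, field: str | None = None, sd_mode: str = "population"
) -> tuple[float, float]:
    """Arithmetic mean and standard deviation of a field or sequence.

    ``sd_mode='population'`` uses divisor n (this reproduces the
    reference cohort's printed mean +/- SD pairs); ``'sample'`` uses
    n - 1.
    """
    if isinstance(values, pd.DataFrame):
        if field is None:
            raise ValueError("field required with a table input")
        data = values[field].dropna().to_numpy(dtype=float)
    else:
        data = np.asarray(values, dtype=float)
        data = data[np.isfinite(data)]
    if data.size == 0:
        raise ValueError("no values to summarize")
    if sd_mode not in ("population", "sample"):
        raise ValueError("sd_mode must be 'population' or 'sample'")
    ddof = 0 if sd_mode == "population" else 1
    if data.size == 1 and ddof == 1:
        raise ValueError("sample SD undefined for a single value")
    return float(data.mean()), float(data.std(ddof=ddof))


def agreement_regression(x, y) -> tuple[float, float]:
    """Through-origin linear regression: slope and (uncentered) R^2.

    slope = sum(x*y) / sum(x^2); R^2 = 1 - sum((y - b x)^2) / sum(y^2),
    the uncentered convention appropriate for a zero-intercept fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("all x are zero")
    slope = float(np.sum(x * y)) / sxx
    syy = float(np.sum(y * y))
    if syy == 0:
        return slope, 1.0
    r2 = 1.0 - float(np.sum((y - slope * x) ** 2)) / syy
    return slope, r2
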
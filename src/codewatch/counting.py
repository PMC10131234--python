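"""Aggregate coded events into per-practice monthly counts and rates.

The pipeline's unit of observation is the (practice, code, month) cell: how
many times a clinical code was recorded at a general practice in a calendar
month.  Occurrences are counted, not unique patients -- repeated recordings on
the same patient each count.  Rates are per 1000 registered patients, using
each practice's list size at the study index date as a fixed denominator for
every month (the convention that produces a small undercount in the earliest
months, since only patients registered at the end of the study contribute
events).

Canonical frames
----------------
``EventCounts``: columns ``practice, code, month, count`` (month is a monthly
``Period``; absent rows mean zero).  ``RateTable``: columns ``practice, code,
month, rate`` -- a *dense* grid over practices x subjects x months, zero-filled,
so that medians and deciles across practices include zero-activity practices.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .months import month_range, parse_month
from .terminology import CodeGroup

__all__ = [
    "count_events",
    "aggregate_group_counts",
    "compute_rates",
    "total_counts",
    "validate_counts",
]

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["practice", "code", "month", "count"]
RATE_COLUMNS = ["practice", "code", "month", "rate"]


def _parse_month_column(df: pd.DataFrame) -> pd.Series:
    """Derive a monthly Period series from a ``month`` or ``date`` column."""
    if "month" in df.columns:
        raw = df["month"]
    elif "date" in df.columns:
        raw = df["date"]
    else:
        raise ValueError("event table needs a 'month' or 'date' column")
    if isinstance(raw.dtype, pd.PeriodDtype):
        return pd.Series(pd.PeriodIndex(raw).asfreq("M"), index=df.index)
    if pd.api.types.is_datetime64_any_dtype(raw):
        return pd.Series(raw.dt.to_period("M"), index=df.index)
    try:
        return pd.Series(pd.PeriodIndex(raw, freq="M"), index=df.index)
    except Exception:
        # locate the offending row for the error message
        for i, v in enumerate(raw):
            try:
                parse_month(v)
            except ValueError:
                raise ValueError(
                    f"row {i}: malformed month/date {v!r} (expected ISO-8601)"
                ) from None
        raise


def count_events(raw: pd.DataFrame, window) -> pd.DataFrame:
    """Tally events per (practice, code, month) within the study window.

    Parameters
    ----------
    raw :
        Either one row per event (columns ``practice, code, date|month``) or a
        pre-aggregated table with an additional non-negative ``count`` column.
    window :
        ``(first_month, last_month)`` inclusive; rows outside are dropped and
        the exclusion tally is logged.

    Returns
    -------
    DataFrame with columns ``practice, code, month, count``, one row per
    observed cell, sorted.  Row order of the input does not matter.
    """
    for col in ("practice", "code"):
        if col not in raw.columns:
            raise ValueError(f"event table missing column {col!r}")
    start, end = (parse_month(window[0]), parse_month(window[1]))

    df = raw.copy()
    df["month"] = _parse_month_column(df)
    if "count" in df.columns:
        counts = pd.to_numeric(df["count"], errors="raise")
        if (counts < 0).any():
            row = int(np.flatnonzero(counts < 0)[0])
            raise ValueError(f"row {row}: negative count {counts.iloc[row]}")
        df["count"] = counts.astype(np.int64)
    else:
        df["count"] = np.int64(1)

    in_window = (df["month"] >= start) & (df["month"] <= end)
    n_dropped = int((~in_window).sum())
    if n_dropped:
        logger.info(
            "count_events: dropped %d of %d rows outside window %s..%s",
            n_dropped, len(df), start, end,
        )
    out = (
        df.loc[in_window, COUNT_COLUMNS]
        .groupby(["practice", "code", "month"], as_index=False, observed=True)["count"]
        .sum()
        .sort_values(["practice", "code", "month"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Check an EventCounts frame's shape and invariants; returns it unchanged."""
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"counts frame missing columns: {missing}")
    if (counts["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    return counts


def aggregate_group_counts(counts: pd.DataFrame, group: CodeGroup) -> pd.DataFrame:
    """Roll member-code counts up to a single group-level series.

    Membership is a set: a code listed twice in the definition contributes
    once.  The output uses ``group.name`` in the ``code`` column.
    """
    validate_counts(counts)
    sub = counts[counts["code"].isin(group.member_codes)]
    out = (
        sub.groupby(["practice", "month"], as_index=False, observed=True)["count"]
        .sum()
        .assign(code=group.name)
        .loc[:, COUNT_COLUMNS]
        .sort_values(["practice", "month"], kind="stable")
        .reset_index(drop=True)
    )
    return out


def compute_rates(
    counts: pd.DataFrame,
    registry: pd.DataFrame,
    *,
    subjects: Iterable[str] | None = None,
    window=None,
) -> pd.DataFrame:
    """Convert counts to monthly rates per 1000 registered patients.

    rate = 1000 x count / list_size, with the registry's index-date list size
    as the denominator for every month.  The result is dense: every registry
    practice gets an explicit (possibly 0.0) rate for every subject and month,
    so downstream deciles include zero-activity practices.

    Parameters
    ----------
    counts :
        EventCounts frame (code column may hold codes or group names).
    registry :
        Practice registry with columns ``practice, list_size``; every practice
        appearing in ``counts`` must be present, with list_size >= 1.
    subjects :
        Codes/groups to measure; defaults to those present in ``counts``.
    window :
        ``(first, last)`` months for the dense grid; defaults to the span of
        ``counts``.
    """
    validate_counts(counts)
    if not {"practice", "list_size"}.issubset(registry.columns):
        raise ValueError("registry needs columns practice, list_size")
    sizes = registry.set_index("practice")["list_size"]
    if sizes.index.has_duplicates:
        dup = sizes.index[sizes.index.duplicated()][0]
        raise ValueError(f"registry lists practice {dup!r} more than once")
    if (sizes < 1).any():
        bad = sizes.index[sizes < 1][0]
        raise ValueError(f"practice {bad!r} has list_size < 1")
    unknown = set(counts["practice"]) - set(sizes.index)
    if unknown:
        raise KeyError(
            f"practices in counts but not in registry: {sorted(unknown)[:5]}"
        )

    if subjects is None:
        subjects = sorted(counts["code"].unique())
    else:
        subjects = sorted(set(subjects))
    if window is None:
        if counts.empty:
            raise ValueError("cannot infer window from empty counts")
        months = month_range(counts["month"].min(), counts["month"].max())
    else:
        months = month_range(window[0], window[1])

    practices = sorted(sizes.index)
    grid = pd.MultiIndex.from_product(
        [practices, subjects, months], names=["practice", "code", "month"]
    )
    filled = (
        counts[counts["code"].isin(subjects)]
        .set_index(["practice", "code", "month"])["count"]
        .reindex(grid, fill_value=0)
        .reset_index()
    )
    filled["rate"] = 1000.0 * filled["count"] / filled["practice"].map(sizes).to_numpy()
    return filled.loc[:, RATE_COLUMNS]


def total_counts(counts: pd.DataFrame, subject: str | None = None) -> pd.Series:
    """Monthly totals across all practices (optionally for one code/group).

    Used for newly introduced codes whose practice deciles are mostly zero and
    where the total volume is the informative series.
    """
    validate_counts(counts)
    df = counts
    if subject is not None:
        if subject not in set(df["code"]):
            raise KeyError(f"subject {subject!r} not present in counts")
        df = df[df["code"] == subject]
    return df.groupby("month", observed=True)["count"].sum().sort_index()
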
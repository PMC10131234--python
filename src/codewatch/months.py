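"""Calendar-month keys for the study window.

All time indexing in the package is by calendar month, represented as pandas
``Period`` objects with monthly frequency and serialised as ``YYYY-MM``.
Event dates are parsed as ISO-8601 and truncated to their month.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["parse_month", "month_range", "months_between"]


def parse_month(value) -> pd.Period:
    """Coerce ``value`` (``"2020-04"``, a date, or a Period) to a monthly Period."""
    if isinstance(value, pd.Period):
        if value.freqstr.startswith("M"):
            return value
        return value.asfreq("M")
    try:
        return pd.Period(value, freq="M")
    except Exception as exc:  # noqa: BLE001 - normalise pandas' parse errors
        raise ValueError(f"cannot interpret {value!r} as a calendar month") from exc


def month_range(start, end) -> pd.PeriodIndex:
    """Inclusive range of months from ``start`` to ``end``."""
    s, e = parse_month(start), parse_month(end)
    if e < s:
        raise ValueError(f"month range end {e} precedes start {s}")
    return pd.period_range(s, e, freq="M")


def months_between(later, earlier) -> int:
    """Number of months from ``earlier`` to ``later`` (positive if later is after)."""
    return (parse_month(later) - parse_month(earlier)).n
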
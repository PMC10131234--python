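"""Summary measures: practice deciles, year-on-year change, recovery classes.

The observatory's display unit is the monthly distribution of a code's (or
group's) rate per 1000 registered patients *across practices*: the median and
the 10th-90th percentiles, plotted over the study window.  Disruption is then
quantified as the year-on-year percentage change of the median series --
100 * (median_t - median_{t-12}) / median_{t-12} -- which cancels seasonality
by construction, and summarised at key months.  A small taxonomy turns the
(nadir change, terminal change) pair into a recovery category.

Quantile rule: linear interpolation between order statistics by default
(configurable; recorded in output metadata so results are reproducible
bit-for-bit given the rule).  Rounding to 1 decimal place, half away from
zero, happens only at the reporting boundary; all computation is at full
precision -- in particular the percent change is computed *before* rounding
the medians.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .months import parse_month

__all__ = [
    "DecileSummary",
    "ChangePoint",
    "RecoveryThresholds",
    "RecoveryClassification",
    "DECILE_LEVELS",
    "practice_deciles",
    "decile_table",
    "median_series",
    "pct_change_yoy",
    "change_frame",
    "format_cell",
    "key_month_summary",
    "classify_recovery",
]

DECILE_LEVELS = (10, 20, 30, 40, 50, 60, 70, 80, 90)


@dataclass(frozen=True)
class DecileSummary:
    """Deciles of one subject's practice-rate distribution in one month."""

    subject: str
    month: pd.Period
    deciles: dict[int, float]
    n_practices: int

    @property
    def median(self) -> float:
        return self.deciles[50]


@dataclass(frozen=True)
class ChangePoint:
    """Year-on-year change of the median rate at one month.

    ``pct_change`` is ``None`` (undefined) when the baseline median 12 months
    earlier is zero or missing -- never coerced to 0 or infinity.  A positive
    baseline with a current median of zero is well-defined and yields -100.0.
    """

    subject: str
    month: pd.Period
    median_rate: float
    pct_change: float | None
    baseline_month: pd.Period

    @property
    def defined(self) -> bool:
        return self.pct_change is not None


def practice_deciles(
    rates: pd.DataFrame,
    subject: str,
    month,
    *,
    quantile_rule: str = "linear",
) -> DecileSummary:
    """Deciles (10th..90th percentile) of per-practice rates for one cell.

    ``rates`` is a dense RateTable (zero-filled over all registry practices);
    the decile vector therefore includes zero-activity practices.  The
    ``quantile_rule`` names a numpy quantile method; the default interpolates
    linearly between order statistics.
    """
    m = parse_month(month)
    vec = rates.loc[
        (rates["code"] == subject) & (rates["month"] == m), "rate"
    ].to_numpy()
    if vec.size == 0:
        raise ValueError(f"no practice rates for subject {subject!r} in {m}")
    qs = np.quantile(vec, [q / 100 for q in DECILE_LEVELS], method=quantile_rule)
    return DecileSummary(
        subject=subject,
        month=m,
        deciles={q: float(v) for q, v in zip(DECILE_LEVELS, qs)},
        n_practices=int(vec.size),
    )


def decile_table(
    rates: pd.DataFrame,
    *,
    quantile_rule: str = "linear",
) -> pd.DataFrame:
    """Tidy decile summaries for every (subject, month) in a RateTable.

    Columns: subject, month, d10..d90, n_practices.  Vectorised equivalent of
    calling :func:`practice_deciles` per cell.
    """
    if rates.empty:
        raise ValueError("empty rate table")
    q_levels = [q / 100 for q in DECILE_LEVELS]

    def summarise(g: pd.Series) -> pd.Series:
        qs = np.quantile(g.to_numpy(), q_levels, method=quantile_rule)
        out = {f"d{q}": v for q, v in zip(DECILE_LEVELS, qs)}
        out["n_practices"] = g.size
        return pd.Series(out)

    tbl = (
        rates.groupby(["code", "month"], observed=True)["rate"]
        .apply(summarise)
        .unstack()
        .reset_index()
        .rename(columns={"code": "subject"})
    )
    tbl["n_practices"] = tbl["n_practices"].astype(int)
    return tbl.sort_values(["subject", "month"], kind="stable").reset_index(drop=True)


def median_series(
    rates: pd.DataFrame,
    subject: str,
    *,
    quantile_rule: str = "linear",
) -> pd.Series:
    """The subject's median rate across practices, indexed by month."""
    sub = rates[rates["code"] == subject]
    if sub.empty:
        raise ValueError(f"subject {subject!r} not in rate table")
    return (
        sub.groupby("month", observed=True)["rate"]
        .apply(lambda v: float(np.quantile(v.to_numpy(), 0.5, method=quantile_rule)))
        .sort_index()
    )


def pct_change_yoy(series: pd.Series, subject: str = "") -> list[ChangePoint]:
    """Year-on-year percent change of a monthly median series.

    For each month with a baseline 12 months earlier in the series:
    100 * (m_t - m_{t-12}) / m_{t-12}; undefined (None) when the baseline is
    zero.  Months without a baseline are omitted.
    """
    series = series.sort_index()
    if len(series) < 13:
        raise ValueError("need at least 13 months to compute year-on-year change")
    out: list[ChangePoint] = []
    for month, value in series.items():
        base_month = month - 12
        if base_month not in series.index:
            continue
        base = series[base_month]
        pct = 100.0 * (value - base) / base if base > 0 else None
        out.append(
            ChangePoint(
                subject=subject,
                month=month,
                median_rate=float(value),
                pct_change=pct,
                baseline_month=base_month,
            )
        )
    return out


def change_frame(changes: Iterable[ChangePoint]) -> pd.DataFrame:
    """ChangePoints as a tidy frame (pct_change NaN where undefined)."""
    return pd.DataFrame(
        [
            {
                "subject": c.subject,
                "month": c.month,
                "median_rate": c.median_rate,
                "pct_change": np.nan if c.pct_change is None else c.pct_change,
                "baseline_month": c.baseline_month,
            }
            for c in changes
        ]
    )


def _round1(x: float) -> Decimal:
    # Reporting rounding: 1 decimal place, ties away from zero.
    return Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)


def format_cell(median: float, pct_change: float | None) -> str:
    """Render a key-month cell: ``"19.8 (-86.9%)"``, ``"6.5 (+12.0%)"``.

    Positive changes carry an explicit plus sign.  An undefined change (zero
    baseline) renders the median with a trailing ``*`` footnote flag.
    """
    m = _round1(median)
    if pct_change is None:
        return f"{m}*"
    p = _round1(pct_change)
    if p == 0:
        p = abs(p)  # never render "-0.0"
    sign = "+" if p > 0 else ""
    return f"{m} ({sign}{p}%)"


def key_month_summary(
    medians: dict[str, pd.Series],
    changes: dict[str, list[ChangePoint]],
    months: Sequence,
) -> pd.DataFrame:
    """One row per subject, one formatted cell per requested key month.

    ``medians`` maps subject -> median series; ``changes`` maps subject ->
    its year-on-year ChangePoints.  Cells render the median rate and percent
    change at 1 decimal place; months whose change is undefined or absent
    carry the ``*`` flag.
    """
    key_months = [parse_month(m) for m in months]
    rows = []
    for subject in sorted(medians):
        series = medians[subject]
        by_month = {c.month: c for c in changes.get(subject, [])}
        row: dict[str, object] = {"subject": subject}
        for m in key_months:
            if m not in series.index:
                raise ValueError(f"key month {m} outside the measured window")
            cp = by_month.get(m)
            row[str(m)] = format_cell(
                series[m], cp.pct_change if cp is not None else None
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject", *[str(m) for m in key_months]])


@dataclass(frozen=True)
class RecoveryThresholds:
    """Cut points (percent) for the disruption/recovery taxonomy.

    A subject whose nadir change never falls below ``maintained_drop`` was
    maintained; otherwise the terminal change decides: above
    ``increase_terminal`` is an increase, within (``recovered_lower``,
    ``increase_terminal``] recovered, within (``partial_lower``,
    ``recovered_lower``] a partial recovery, and at or below
    ``partial_lower`` a sustained drop.
    """

    maintained_drop: float = -20.0
    increase_terminal: float = 10.0
    recovered_lower: float = -10.0
    partial_lower: float = -30.0


@dataclass(frozen=True)
class RecoveryClassification:
    subject: str
    drop_pct: float
    terminal_pct: float
    category: str


def classify_recovery(
    changes: Sequence[ChangePoint],
    *,
    thresholds: RecoveryThresholds = RecoveryThresholds(),
    disruption_start=None,
    terminal_month=None,
) -> RecoveryClassification:
    """Classify a subject's disruption/recovery pattern.

    The nadir is the most negative defined change within the disruption
    window (months >= ``disruption_start``; the whole series if omitted); the
    terminal change is the defined change at ``terminal_month`` (default: the
    last defined month).  Raises if no change in the window is defined.
    """
    defined = [c for c in changes if c.defined]
    if disruption_start is not None:
        d0 = parse_month(disruption_start)
        defined = [c for c in defined if c.month >= d0]
    if not defined:
        raise ValueError("no defined year-on-year changes in the disruption window")
    drop = min(c.pct_change for c in defined)  # type: ignore[type-var]
    if terminal_month is not None:
        tm = parse_month(terminal_month)
        terminal_cp = next((c for c in defined if c.month == tm), None)
        if terminal_cp is None:
            raise ValueError(f"no defined change at terminal month {tm}")
    else:
        terminal_cp = max(defined, key=lambda c: c.month)
    terminal = terminal_cp.pct_change
    assert terminal is not None

    t = thresholds
    if drop > t.maintained_drop:
        category = "maintained"
    elif terminal > t.increase_terminal:
        category = "increase"
    elif terminal > t.recovered_lower:
        category = "recovered"
    elif terminal > t.partial_lower:
        category = "partial_recovery"
    else:
        category = "sustained_drop"
    return RecoveryClassification(
        subject=changes[0].subject if changes else "",
        drop_pct=float(drop),
        terminal_pct=float(terminal),
        category=category,
    )
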
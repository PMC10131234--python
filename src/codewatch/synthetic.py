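"""Synthetic primary-care coded-activity generator.

Real practice-level EHR event tables cannot be redistributed, so the pipeline
is exercised end-to-end on simulated data with known ground truth.  The
generator emulates the salient features of national primary-care activity
data:

* a few thousand practices with log-normally heterogeneous list sizes;
* a heavy-tailed (log-normal) distribution of per-code baseline monthly rates,
  so a handful of codes dominate volume while most are rare;
* a persistent multiplicative practice effect (log-normal, constant over
  time), which is what produces the wide but stable between-practice decile
  spread seen in practice-level measures;
* sinusoidal seasonality;
* overdispersed monthly counts (gamma-Poisson / NB2, var = mu + alpha*mu^2,
  with the Poisson limit at alpha = 0);
* an abrupt, configurable disruption (an April-2020 analogue) with a choice of
  recovery trajectories toward a configurable terminal level;
* the early-month undercount induced by fixing the denominator cohort at the
  study end date, modelled as month-dependent binomial thinning that tapers
  linearly from ``attrition_fraction_start`` at the first study month to zero
  at the index month.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
import string
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counting import COUNT_COLUMNS, validate_counts
from .months import month_range, months_between, parse_month
from .terminology import ClinicalCode, CodeHierarchy

__all__ = [
    "Practice",
    "DisruptionProfile",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_practices",
    "generate_base_rates",
    "generate_events",
    "apply_index_date_attrition",
    "generate_toy_terminology",
    "generate_dataset",
]

RECOVERY_SHAPES = ("none", "linear", "exponential", "overshoot")

# Seed offsets for the independent random streams of each generation stage.
_STREAM_PRACTICES = 1
_STREAM_TERMINOLOGY = 2
_STREAM_RATES = 3
_STREAM_EVENTS = 4
_STREAM_ATTRITION = 5


@dataclass(frozen=True)
class Practice:
    """A general practice: identifier and registered-patient list size at the index date."""

    practice_id: str
    list_size: int

    def __post_init__(self) -> None:
        if self.list_size < 1:
            raise ValueError("list_size must be >= 1")


@dataclass(frozen=True)
class DisruptionProfile:
    """Multiplicative trajectory applied to a code's expected rate.

    The multiplier m(t) is 1 before ``disruption_month``, drops to
    ``1 - drop_fraction`` at the disruption month, then moves toward
    ``terminal_level`` (1.0 = full recovery, 0.6 = sustained 40% drop,
    1.2 = increase) which is reached exactly ``recovery_months`` months after
    the disruption and held thereafter.

    Shapes: ``none`` stays at the dropped level (terminal_level ignored);
    ``linear`` interpolates; ``exponential`` approaches the terminal level
    with a time constant of recovery_months/3 (clamped at the terminal level
    once recovery_months have elapsed); ``overshoot`` follows the linear path
    plus a half-sine excursion beyond the terminal level, peaking mid-recovery.
    """

    disruption_month: str = "2020-04"
    drop_fraction: float = 0.6
    recovery_shape: str = "linear"
    recovery_months: int = 8
    terminal_level: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.drop_fraction <= 1.0:
            raise ValueError("drop_fraction must be in [0, 1]")
        if self.recovery_shape not in RECOVERY_SHAPES:
            raise ValueError(f"recovery_shape must be one of {RECOVERY_SHAPES}")
        if self.recovery_months < 1:
            raise ValueError("recovery_months must be >= 1")
        if self.terminal_level <= 0:
            raise ValueError("terminal_level must be > 0")

    def multiplier(self, months) -> np.ndarray:
        """Evaluate m(t) over an iterable of months."""
        d0 = parse_month(self.disruption_month)
        low = 1.0 - self.drop_fraction
        term = self.terminal_level
        R = self.recovery_months
        out = np.empty(len(months), dtype=float)
        for i, m in enumerate(months):
            k = months_between(m, d0)
            if k < 0:
                out[i] = 1.0
            elif self.recovery_shape == "none":
                out[i] = low
            elif k >= R:
                out[i] = term
            elif self.recovery_shape == "linear":
                out[i] = low + (term - low) * k / R
            elif self.recovery_shape == "exponential":
                out[i] = term + (low - term) * math.exp(-3.0 * k / R)
            else:  # overshoot
                lin = low + (term - low) * k / R
                out[i] = lin + 0.25 * (term - low) * math.sin(math.pi * k / R)
        return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters.

    Defaults reflect the target study's conditions: 2500 practices over a
    24-month window (Jan 2019 - Dec 2020) with the population fixed on the
    31 Dec 2020 index date and an early-period undercount of up to 7%.
    List sizes are log-normal around a typical English practice (~8000
    patients); per-code baseline rates are log-normal with a heavy tail
    (median 2 events per 1000 patients per month, sdlog 1.5) so volumes span
    several orders of magnitude.
    """

    n_practices: int = 2500
    list_size_meanlog: float = math.log(8000.0)
    list_size_sdlog: float = 0.5
    n_codes: int = 60
    base_rate_meanlog: float = math.log(2.0)
    base_rate_sdlog: float = 1.5
    practice_effect_sd: float = 0.35
    seasonality_amplitude: float = 0.10
    seasonality_peak_month: int = 1
    dispersion: float = 0.15
    study_start: str = "2019-01"
    study_end: str = "2020-12"
    index_date: str = "2020-12-31"
    attrition_fraction_start: float = 0.07
    keywords: tuple[str, ...] = (
        "review", "screening", "monitoring", "examination", "smear", "medication",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_practices < 1:
            raise ValueError("n_practices must be >= 1")
        if self.n_codes < 1:
            raise ValueError("n_codes must be >= 1")
        if self.list_size_sdlog < 0 or self.base_rate_sdlog < 0:
            raise ValueError("sdlog parameters must be >= 0")
        if self.practice_effect_sd < 0:
            raise ValueError("practice_effect_sd must be >= 0")
        if not 0.0 <= self.seasonality_amplitude < 1.0:
            raise ValueError("seasonality_amplitude must be in [0, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.attrition_fraction_start <= 0.1:
            raise ValueError("attrition_fraction_start must be in [0, 0.1]")
        if parse_month(self.study_end) < parse_month(self.study_start):
            raise ValueError("study_end precedes study_start")

    @property
    def months(self) -> pd.PeriodIndex:
        return month_range(self.study_start, self.study_end)

    def seasonality(self, months) -> np.ndarray:
        """Multiplicative seasonal factor, mean ~1, peaking at seasonality_peak_month."""
        phase = np.array([m.month for m in months], dtype=float)
        return 1.0 + self.seasonality_amplitude * np.cos(
            2.0 * np.pi * (phase - self.seasonality_peak_month) / 12.0
        )

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


def generate_practices(config: SyntheticConfig) -> pd.DataFrame:
    """Draw the practice registry: columns ``practice, list_size``.

    List sizes are log-normal(meanlog, sdlog), rounded and floored at 1.
    """
    rng = config._rng(_STREAM_PRACTICES)
    sizes = np.exp(
        rng.normal(config.list_size_meanlog, config.list_size_sdlog, config.n_practices)
    )
    sizes = np.maximum(1, np.rint(sizes).astype(np.int64))
    width = len(str(config.n_practices))
    ids = [f"P{i:0{width}d}" for i in range(1, config.n_practices + 1)]
    return pd.DataFrame({"practice": ids, "list_size": sizes})


def generate_base_rates(config: SyntheticConfig, code_ids) -> pd.Series:
    """Per-code mean monthly rate per 1000 patients, log-normal heavy-tailed."""
    rng = config._rng(_STREAM_RATES)
    rates = np.exp(
        rng.normal(config.base_rate_meanlog, config.base_rate_sdlog, len(code_ids))
    )
    return pd.Series(rates, index=list(code_ids), name="base_rate")


def generate_events(
    config: SyntheticConfig,
    practices: pd.DataFrame,
    code_rates: Mapping[str, float] | pd.Series,
    profiles: Mapping[str, DisruptionProfile] | None = None,
    *,
    introductions: Mapping[str, object] | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate the monthly event-count table.

    For practice p, code c, month t the expected count is::

        mu = list_size_p / 1000 * base_rate_c * effect_p * season(t) * m_c(t)

    where ``effect_p`` is log-normal with sd ``practice_effect_sd`` (median 1)
    and ``m_c(t)`` is the code's disruption multiplier (1 if unprofiled).
    Counts are gamma-Poisson with var = mu + dispersion * mu^2 (Poisson when
    dispersion = 0).  Codes listed in ``introductions`` have expectation 0
    before their introduction month (newly introduced concepts, e.g. a
    structured-medication-review code appearing mid-study).

    Returns an EventCounts frame (zero cells omitted).
    """
    profiles = dict(profiles or {})
    code_rates = pd.Series(code_rates, dtype=float)
    missing = [c for c in profiles if c not in code_rates.index]
    if missing:
        raise ValueError(f"profiled codes without a base rate: {missing}")
    if rng is None:
        rng = config._rng(_STREAM_EVENTS)

    months = config.months
    codes = list(code_rates.index)
    sizes = practices["list_size"].to_numpy(dtype=float)
    n_p, n_c, n_t = len(practices), len(codes), len(months)

    effects = np.exp(rng.normal(0.0, config.practice_effect_sd, n_p))
    season = config.seasonality(months)

    mult = np.ones((n_c, n_t))
    for j, c in enumerate(codes):
        if c in profiles:
            mult[j] = profiles[c].multiplier(months)
    if introductions:
        for c, intro in introductions.items():
            if c not in code_rates.index:
                raise ValueError(f"introduced code {c!r} has no base rate")
            j = codes.index(c)
            intro_m = parse_month(intro)
            mult[j] *= np.array([1.0 if m >= intro_m else 0.0 for m in months])

    # mu[p, c, t], built from broadcastable factors
    mu = (
        (sizes / 1000.0 * effects)[:, None, None]
        * code_rates.to_numpy()[None, :, None]
        * mult[None, :, :]
        * season[None, None, :]
    )
    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, config.dispersion * mu)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)

    df = pd.DataFrame(
        {
            "practice": np.repeat(practices["practice"].to_numpy(), n_c * n_t),
            "code": np.tile(np.repeat(np.array(codes, dtype=object), n_t), n_p),
            "month": np.tile(months.to_numpy(), n_p * n_c),
            "count": counts.reshape(-1),
        }
    )
    df = df[df["count"] > 0].reset_index(drop=True)
    return df.loc[:, COUNT_COLUMNS]


def apply_index_date_attrition(
    counts: pd.DataFrame,
    config: SyntheticConfig,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Thin counts to emulate the fixed index-date denominator cohort.

    Counting only events of patients registered at the study end date loses
    the activity of patients who died or deregistered earlier, so observed
    totals fall short of database totals by a fraction that is largest at the
    start of the study and vanishes by the index month.  Each count is thinned
    binomially with retention 1 - a(t), where a(t) declines linearly from
    ``attrition_fraction_start`` at the first study month to 0 at the index
    month.
    """
    validate_counts(counts)
    a0 = config.attrition_fraction_start
    if a0 == 0 or counts.empty:
        return counts.copy()
    if rng is None:
        rng = config._rng(_STREAM_ATTRITION)
    first = parse_month(config.study_start)
    index_m = parse_month(config.index_date)
    span = months_between(index_m, first)
    out = counts.copy()
    elapsed = np.array([months_between(m, first) for m in out["month"]], dtype=float)
    frac = a0 * np.clip(1.0 - elapsed / span, 0.0, 1.0) if span > 0 else np.zeros(len(out))
    out["count"] = rng.binomial(out["count"].to_numpy(), 1.0 - frac)
    out = out[out["count"] > 0].reset_index(drop=True)
    return out


# Vocabulary for synthetic code descriptions; the configured keywords are
# guaranteed each to appear in at least one description.
_NOUNS = (
    "blood pressure", "cervical", "diabetic", "cardiovascular", "depression",
    "renal function", "cholesterol", "asthma", "thyroid", "contraception",
    "pregnancy", "foot", "retinopathy", "bowel", "haemoglobin",
)
_TAILS = ("done", "declined", "result", "programme", "interim", "completed", "requested")

_CODE_ALPHABET = string.digits + string.ascii_uppercase


def generate_toy_terminology(config: SyntheticConfig) -> CodeHierarchy:
    """Build a small CTV3-like forest for exercising grouping and search.

    Codes are 5 characters with prefix-consistent structure over 2-3 levels:
    roots ``XX000``, mid-level ``XXY00``, leaves ``XXYZZ`` (so prefix groups on
    the leading 2-3 characters coincide with subtrees).  Descriptions are
    seeded keyword/noun compositions so keyword search has guaranteed hits.
    """
    rng = config._rng(_STREAM_TERMINOLOGY)
    n = config.n_codes
    codes: list[ClinicalCode] = []

    n_roots = max(1, n // 12)
    root_prefixes: list[str] = []
    while len(root_prefixes) < n_roots:
        p = "".join(rng.choice(list(_CODE_ALPHABET), size=2))
        if p not in root_prefixes:
            root_prefixes.append(p)

    def describe(i: int) -> str:
        kw = config.keywords[i % len(config.keywords)] if config.keywords else ""
        noun = _NOUNS[int(rng.integers(len(_NOUNS)))]
        tail = _TAILS[int(rng.integers(len(_TAILS)))]
        return f"{noun.capitalize()} {kw} {tail}".replace("  ", " ").strip()

    i = 0
    for p in root_prefixes:
        if i >= n:
            break
        codes.append(ClinicalCode(f"{p}000", describe(i), None))
        i += 1
    mids_by_root: dict[str, list[str]] = {p: [] for p in root_prefixes}
    used: set[str] = {c.code_id for c in codes}
    while i < n:
        p = root_prefixes[int(rng.integers(len(root_prefixes)))]
        if not mids_by_root[p] or (len(mids_by_root[p]) < 4 and rng.random() < 0.4):
            ch = _CODE_ALPHABET[int(rng.integers(len(_CODE_ALPHABET)))]
            cid = f"{p}{ch}00"
            if cid in used:
                continue
            codes.append(ClinicalCode(cid, describe(i), f"{p}000"))
            mids_by_root[p].append(cid)
        else:
            mid = mids_by_root[p][int(rng.integers(len(mids_by_root[p])))]
            suffix = "".join(rng.choice(list(_CODE_ALPHABET), size=2))
            cid = f"{mid[:3]}{suffix}"
            if cid in used:
                continue
            codes.append(ClinicalCode(cid, describe(i), mid))
        used.add(cid)
        i += 1
    return CodeHierarchy(codes)


@dataclass(frozen=True)
class SyntheticDataset:
    """One full simulated study: registry, terminology, ground truth and counts."""

    config: SyntheticConfig
    practices: pd.DataFrame
    hierarchy: CodeHierarchy
    base_rates: pd.Series
    profiles: dict[str, DisruptionProfile]
    counts: pd.DataFrame


def generate_dataset(
    config: SyntheticConfig,
    profiles: Mapping[str, DisruptionProfile] | DisruptionProfile | None = None,
    *,
    introductions: Mapping[str, object] | None = None,
) -> SyntheticDataset:
    """Run the full generation pipeline deterministically from the config seed.

    ``profiles`` may map individual codes to disruption profiles, or be a
    single profile applied to every code.  Attrition is applied last.
    """
    practices = generate_practices(config)
    hierarchy = generate_toy_terminology(config)
    code_ids = sorted(hierarchy.code_ids)
    rates = generate_base_rates(config, code_ids)
    if isinstance(profiles, DisruptionProfile):
        profile_map = {c: profiles for c in code_ids}
    else:
        profile_map = dict(profiles or {})
    counts = generate_events(
        config, practices, rates, profile_map, introductions=introductions
    )
    counts = apply_index_date_attrition(counts, config)
    return SyntheticDataset(
        config=config,
        practices=practices,
        hierarchy=hierarchy,
        base_rates=rates,
        profiles=profile_map,
        counts=counts,
    )
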
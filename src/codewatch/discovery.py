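"""Data-driven selection of high-volume codes and topic assignment.

Rather than starting from manually curated code lists, the observatory
approach surveys *all* coded activity, keeps the codes busy enough to matter
(a threshold on total occurrences in a reference year; the convention here is
that a total of exactly the threshold is retained, i.e. codes *below* it are
excluded), and organises the survivors into broad clinical topics via ordered
rules combining code prefixes, description keywords and explicit lists.
Codes may belong to several topics; codes matching no rule land in the
reserved topic ``"unclassified"``.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import pandas as pd

from .counting import validate_counts
from .terminology import CodeGroup, CodeHierarchy

__all__ = [
    "TopicRule",
    "DiscoveryConfig",
    "OverlapReport",
    "frequency_filter",
    "year_totals",
    "assign_topics",
    "resolve_overlaps",
    "selection_table",
]

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class TopicRule:
    """One topic with its membership rules (prefixes, keywords, explicit codes)."""

    name: str
    prefixes: tuple[str, ...] = ()
    keywords: tuple[str, ...] = ()
    codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "prefixes", tuple(self.prefixes))
        object.__setattr__(self, "keywords", tuple(self.keywords))
        object.__setattr__(self, "codes", tuple(self.codes))


@dataclass(frozen=True)
class DiscoveryConfig:
    """Frequency-threshold and topic-rule configuration.

    ``threshold`` is the minimum total occurrences over all practices in
    ``threshold_year`` for a code to be retained (default 1000 in the 2020
    analogue year).  ``exclusions`` are code prefixes removed before
    selection regardless of volume (a full code is its own prefix) --
    the stand-in for record types, such as medication and vaccination
    entries, that the surveillance deliberately leaves to other tools.
    """

    threshold: int = 1000
    threshold_year: int = 2020
    topic_rules: tuple[TopicRule, ...] = ()
    exclusions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold must be >= 1")
        names = [r.name for r in self.topic_rules]
        if len(names) != len(set(names)):
            raise ValueError("topic names must be unique")
        object.__setattr__(self, "topic_rules", tuple(self.topic_rules))
        object.__setattr__(self, "exclusions", tuple(self.exclusions))

    def is_excluded(self, code_id: str) -> bool:
        return any(code_id.startswith(p) for p in self.exclusions)


def year_totals(counts: pd.DataFrame, year: int) -> pd.Series:
    """Total occurrences per code over all practices and months of ``year``."""
    validate_counts(counts)
    in_year = counts["month"].map(lambda m: m.year) == year
    return counts.loc[in_year].groupby("code", observed=True)["count"].sum()


def frequency_filter(counts: pd.DataFrame, cfg: DiscoveryConfig) -> set[str]:
    """Codes whose total count in the threshold year reaches the threshold.

    Totals are over the threshold year only (not the whole study window);
    total == threshold is retained, total < threshold is excluded.  Raises if
    the counts contain no months of the threshold year at all (the threshold
    year must lie inside the study window).
    """
    validate_counts(counts)
    if not counts.empty:
        years = {m.year for m in counts["month"].unique()}
        if cfg.threshold_year not in years:
            raise ValueError(
                f"threshold year {cfg.threshold_year} outside the counts' window "
                f"(years present: {sorted(years)})"
            )
    totals = year_totals(counts, cfg.threshold_year)
    return {
        code
        for code, total in totals.items()
        if total >= cfg.threshold and not cfg.is_excluded(code)
    }


def assign_topics(
    selected: Iterable[str],
    h: CodeHierarchy,
    cfg: DiscoveryConfig,
) -> dict[str, set[str]]:
    """Map each selected code to the set of topics whose rules it satisfies.

    A code matches a topic if it satisfies *any* of that topic's prefix,
    keyword (case-insensitive description substring) or explicit-code rules.
    Membership does not depend on rule order.  Codes matching nothing get
    ``{"unclassified"}``.
    """
    out: dict[str, set[str]] = {}
    for code in selected:
        desc = h.get(code).description.lower() if code in h else ""
        topics: set[str] = set()
        for rule in cfg.topic_rules:
            if (
                any(code.startswith(p) for p in rule.prefixes)
                or any(kw.lower() in desc for kw in rule.keywords)
                or code in rule.codes
            ):
                topics.add(rule.name)
        out[code] = topics or {UNCLASSIFIED}
    return out


@dataclass(frozen=True)
class OverlapReport:
    """Codes shared between groups and group pairs with containment.

    ``shared_codes`` maps each code appearing in more than one group to the
    sorted tuple of group names containing it; ``containments`` lists
    ``(inner, outer)`` pairs where every code of ``inner`` is also in
    ``outer``.  Purely diagnostic -- groups are never mutated.
    """

    shared_codes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    containments: tuple[tuple[str, str], ...] = ()

    @property
    def is_empty(self) -> bool:
        return not self.shared_codes and not self.containments


def resolve_overlaps(groups: Sequence[CodeGroup]) -> OverlapReport:
    """Report every code in more than one group and every containment pair."""
    membership: dict[str, list[str]] = {}
    for g in groups:
        for code in g.member_codes:
            membership.setdefault(code, []).append(g.name)
    shared = {
        code: tuple(sorted(names))
        for code, names in membership.items()
        if len(names) > 1
    }
    contain = []
    for a in groups:
        for b in groups:
            if a.name != b.name and a.member_codes <= b.member_codes:
                contain.append((a.name, b.name))
    return OverlapReport(shared_codes=shared, containments=tuple(sorted(contain)))


def selection_table(
    counts: pd.DataFrame,
    h: CodeHierarchy,
    cfg: DiscoveryConfig,
) -> pd.DataFrame:
    """The discovery output table: code, description, threshold-year total, topics."""
    selected = frequency_filter(counts, cfg)
    totals = year_totals(counts, cfg.threshold_year)
    topics = assign_topics(selected, h, cfg)
    rows = [
        {
            "code": code,
            "description": h.get(code).description if code in h else "",
            "total": int(totals[code]),
            "topics": ";".join(sorted(topics[code])),
        }
        for code in sorted(selected)
    ]
    return pd.DataFrame(rows, columns=["code", "description", "total", "topics"])
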
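import numpy as np
import pandas as pd
import pytest

from codewatch.discovery import (
    DiscoveryConfig,
    TopicRule,
    assign_topics,
    frequency_filter,
    resolve_overlaps,
    selection_table,
)
from codewatch.terminology import (
    ClinicalCode,
    CodeHierarchy,
    GroupDefinition,
    build_group,
)


def year_counts(builder, totals: dict[str, int], year=2020):
    """Spread each code's annual total over months/practices."""
    rows = []
    for code, total in totals.items():
        q, r = divmod(total, 12)
        for m in range(1, 13):
            c = q + (1 if m <= r else 0)
            if c:
                rows.append((f"P{m % 3}", code, f"{year}-{m:02d}", c))
    return builder(rows)


class TestFrequencyFilter:
    def test_threshold_boundary(self, counts_builder):
        counts = year_counts(
            counts_builder, {"under": 999, "at": 1000, "over": 1001}
        )
        assert frequency_filter(counts, DiscoveryConfig()) == {"at", "over"}

    def test_empty_counts_select_nothing(self, counts_builder):
        counts = counts_builder([])
        assert frequency_filter(counts, DiscoveryConfig()) == set()

    def test_threshold_year_must_be_in_window(self, counts_builder):
        counts = year_counts(counts_builder, {"X": 5000}, year=2020)
        with pytest.raises(ValueError, match="2023"):
            frequency_filter(counts, DiscoveryConfig(threshold_year=2023))

    def test_totals_restricted_to_threshold_year(self, counts_builder):
        counts = pd.concat(
            [
                year_counts(counts_builder, {"X": 600}, year=2019),
                year_counts(counts_builder, {"X": 600}, year=2020),
            ],
            ignore_index=True,
        )
        # 1200 over the window but only 600 in 2020: excluded
        assert frequency_filter(counts, DiscoveryConfig()) == set()

    def test_exclusion_prefixes_apply(self, counts_builder):
        counts = year_counts(counts_builder, {"vacc1": 5000, "keep1": 5000})
        cfg = DiscoveryConfig(exclusions=("vacc",))
        assert frequency_filter(counts, cfg) == {"keep1"}

    def test_matches_brute_force_and_is_monotone(self, counts_builder):
        rng = np.random.default_rng(13)
        totals = {f"C{i}": int(rng.integers(0, 200)) for i in range(40)}
        counts = year_counts(counts_builder, {k: v for k, v in totals.items() if v})
        previous: set | None = None
        for threshold in sorted(rng.integers(1, 250, size=20)):
            cfg = DiscoveryConfig(threshold=int(threshold))
            got = frequency_filter(counts, cfg)
            expected = {c for c, t in totals.items() if t >= threshold}
            assert got == expected
            if previous is not None:
                assert got <= previous  # raising the threshold never adds codes
            previous = got

    def test_partitioning_practices_does_not_change_selection(self, counts_builder):
        rng = np.random.default_rng(14)
        rows = [
            (f"P{rng.integers(6)}", f"C{rng.integers(8)}",
             f"2020-{rng.integers(1, 13):02d}", int(rng.integers(1, 40)))
            for _ in range(300)
        ]
        counts = counts_builder(rows)
        cfg = DiscoveryConfig(threshold=300)
        whole = frequency_filter(counts, cfg)
        # recompute from an arbitrary bipartition of practices
        part_a = counts[counts["practice"].isin({"P0", "P1", "P2"})]
        part_b = counts[~counts["practice"].isin({"P0", "P1", "P2"})]
        merged = (
            pd.concat([part_a, part_b])
            .groupby(["practice", "code", "month"], as_index=False)["count"].sum()
        )
        assert frequency_filter(merged, cfg) == whole


class TestTopics:
    @pytest.fixture
    def hierarchy(self):
        return CodeHierarchy(
            [
                ClinicalCode("61abc", "Contraception advice", None),
                ClinicalCode("24abc", "Examination of cardiovascular system", None),
                ClinicalCode("XaIIj", "Diabetic retinopathy screening", None),
                ClinicalCode("Zzzzz", "Completely unrelated admin", None),
            ]
        )

    @pytest.fixture
    def cfg(self):
        return DiscoveryConfig(
            topic_rules=(
                TopicRule("female-reproductive-health", prefixes=("61",)),
                TopicRule("screening", keywords=("screening",)),
                TopicRule("diabetes", keywords=("diabetic",)),
                TopicRule("cardiovascular", prefixes=("24",)),
            )
        )

    def test_prefix_rule_assigns_topic(self, hierarchy, cfg):
        topics = assign_topics({"61abc"}, hierarchy, cfg)
        assert topics["61abc"] == {"female-reproductive-health"}

    def test_multi_topic_membership_retained(self, hierarchy, cfg):
        topics = assign_topics({"XaIIj"}, hierarchy, cfg)
        assert topics["XaIIj"] == {"screening", "diabetes"}

    def test_unmatched_code_is_unclassified(self, hierarchy, cfg):
        assert assign_topics({"Zzzzz"}, hierarchy, cfg)["Zzzzz"] == {"unclassified"}

    def test_rule_order_does_not_affect_membership(self, hierarchy, cfg):
        reordered = DiscoveryConfig(topic_rules=tuple(reversed(cfg.topic_rules)))
        codes = {"61abc", "24abc", "XaIIj", "Zzzzz"}
        assert assign_topics(codes, hierarchy, cfg) == assign_topics(
            codes, hierarchy, reordered
        )

    def test_matches_naive_rule_evaluation(self):
        rng = np.random.default_rng(15)
        words = ["screening", "review", "blood", "foot", "smear"]
        codes = [
            ClinicalCode(
                f"{rng.choice(list('AB'))}{i:03d}x"[:5],
                " ".join(rng.choice(words, 2)),
                None,
            )
            for i in range(50)
        ]
        h = CodeHierarchy(codes)
        rules = (
            TopicRule("t1", prefixes=("A",), keywords=("smear",)),
            TopicRule("t2", keywords=("blood", "foot"), codes=(codes[0].code_id,)),
        )
        cfg = DiscoveryConfig(topic_rules=rules)
        got = assign_topics(h.code_ids, h, cfg)
        for c in codes:
            expected = set()
            for rule in rules:
                hit = (
                    any(c.code_id.startswith(p) for p in rule.prefixes)
                    or any(k in c.description.lower() for k in rule.keywords)
                    or c.code_id in rule.codes
                )
                if hit:
                    expected.add(rule.name)
            assert got[c.code_id] == (expected or {"unclassified"})

    def test_duplicate_topic_names_rejected(self):
        with pytest.raises(ValueError):
            DiscoveryConfig(topic_rules=(TopicRule("a"), TopicRule("a")))


class TestOverlaps:
    def groups(self, h, defs):
        return [build_group(h, d) for d in defs]

    def test_disjoint_groups_give_empty_report(self):
        h = CodeHierarchy([ClinicalCode(c, c, None) for c in ("A0000", "B0000")])
        gs = self.groups(
            h,
            [GroupDefinition("ga", prefix="A"), GroupDefinition("gb", prefix="B")],
        )
        assert resolve_overlaps(gs).is_empty

    def test_prefix_and_explicit_overlap_reported(self):
        h = CodeHierarchy(
            [ClinicalCode("24abc", "x", None), ClinicalCode("24xyz", "y", None)]
        )
        gs = self.groups(
            h,
            [
                GroupDefinition("g24", prefix="24"),
                GroupDefinition("one", members=("24abc",)),
            ],
        )
        report = resolve_overlaps(gs)
        assert report.shared_codes == {"24abc": ("g24", "one")}
        assert ("one", "g24") in report.containments

    def test_matches_pairwise_intersection_oracle(self):
        rng = np.random.default_rng(16)
        universe = [f"U{i:04d}" for i in range(40)]
        h = CodeHierarchy([ClinicalCode(c, c, None) for c in universe])
        gs = []
        for k in range(5):
            size = int(rng.integers(3, 12))
            members = tuple(rng.choice(universe, size=size, replace=False))
            gs.append(build_group(h, GroupDefinition(f"g{k}", members=members)))
        report = resolve_overlaps(gs)
        counted: dict[str, list[str]] = {}
        for g in gs:
            for c in g.member_codes:
                counted.setdefault(c, []).append(g.name)
        expected_shared = {
            c: tuple(sorted(n)) for c, n in counted.items() if len(n) > 1
        }
        assert report.shared_codes == expected_shared
        for a in gs:
            for b in gs:
                if a.name != b.name:
                    contained = a.member_codes <= b.member_codes
                    assert ((a.name, b.name) in report.containments) == contained


def test_selection_table_shape(counts_builder):
    h = CodeHierarchy(
        [
            ClinicalCode("A0000", "Busy code", None),
            ClinicalCode("B0000", "Quiet code", None),
        ]
    )
    counts = year_counts(counts_builder, {"A0000": 150, "B0000": 10})
    cfg = DiscoveryConfig(
        threshold=100, topic_rules=(TopicRule("busy", prefixes=("A",)),)
    )
    table = selection_table(counts, h, cfg)
    assert table.columns.tolist() == ["code", "description", "total", "topics"]
    assert table["code"].tolist() == ["A0000"]
    assert table["total"].tolist() == [150]
    assert table["topics"].tolist() == ["busy"]
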
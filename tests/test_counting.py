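import logging

import numpy as np
import pandas as pd
import pytest

from codewatch.counting import (
    aggregate_group_counts,
    compute_rates,
    count_events,
    total_counts,
)
from codewatch.terminology import ClinicalCode, CodeHierarchy, GroupDefinition, build_group

WINDOW = ("2019-01", "2020-12")


def events(rows, cols=("practice", "code", "date")):
    return pd.DataFrame(rows, columns=list(cols))


class TestCountEvents:
    def test_repeated_events_accumulate(self):
        raw = events(
            [
                ("P1", "X", "2020-03-02"),
                ("P1", "X", "2020-03-15"),
                ("P1", "X", "2020-03-30"),
            ]
        )
        out = count_events(raw, WINDOW)
        assert len(out) == 1
        assert out["count"].iloc[0] == 3
        assert out["month"].iloc[0] == pd.Period("2020-03", "M")

    def test_rows_outside_window_are_dropped_and_logged(self, caplog):
        raw = events(
            [("P1", "X", "2020-12-31"), ("P1", "X", "2021-01-02")]
        )
        with caplog.at_level(logging.INFO, logger="codewatch.counting"):
            out = count_events(raw, WINDOW)
        assert out["count"].sum() == 1
        assert any("dropped 1" in r.message for r in caplog.records)

    def test_malformed_month_error_names_the_row(self):
        raw = events([("P1", "X", "2020-03-01"), ("P1", "X", "not-a-date")])
        with pytest.raises(ValueError, match="row 1"):
            count_events(raw, WINDOW)

    def test_negative_count_rejected(self):
        raw = events(
            [("P1", "X", "2020-03", 5), ("P1", "Y", "2020-03", -2)],
            cols=("practice", "code", "month", "count"),
        )
        with pytest.raises(ValueError, match="negative"):
            count_events(raw, WINDOW)

    def test_matches_hash_map_tally_oracle_and_row_order(self):
        rng = np.random.default_rng(11)
        n = 1000
        raw = events(
            list(
                zip(
                    rng.choice([f"P{i}" for i in range(10)], n),
                    rng.choice(list("ABCDE"), n),
                    rng.choice([f"2020-{m:02d}" for m in range(1, 13)], n),
                )
            ),
            cols=("practice", "code", "month"),
        )
        tally: dict[tuple, int] = {}
        for _, r in raw.iterrows():
            key = (r["practice"], r["code"], pd.Period(r["month"], "M"))
            tally[key] = tally.get(key, 0) + 1
        out = count_events(raw, WINDOW)
        got = {
            (r["practice"], r["code"], r["month"]): r["count"]
            for _, r in out.iterrows()
        }
        assert got == tally
        shuffled = raw.sample(frac=1, random_state=0).reset_index(drop=True)
        assert count_events(shuffled, WINDOW).equals(out)


class TestGroupAggregation:
    def group(self, name, codes):
        h = CodeHierarchy([ClinicalCode(c, c, None) for c in codes])
        return build_group(h, GroupDefinition(name, members=tuple(codes)))

    def test_member_counts_sum(self, counts_builder):
        counts = counts_builder(
            [("P1", "A", "2020-01", 2), ("P1", "B", "2020-01", 3)]
        )
        out = aggregate_group_counts(counts, self.group("ab", ["A", "B"]))
        assert out["count"].tolist() == [5]
        assert out["code"].iloc[0] == "ab"

    def test_single_code_group_is_identity(self, counts_builder):
        counts = counts_builder(
            [("P1", "A", "2020-01", 2), ("P2", "A", "2020-02", 7)]
        )
        out = aggregate_group_counts(counts, self.group("solo", ["A"]))
        assert out["count"].tolist() == counts["count"].tolist()

    def test_matches_brute_force_summation(self, counts_builder):
        rng = np.random.default_rng(3)
        rows = [
            (f"P{rng.integers(5)}", rng.choice(list("ABCDEF")),
             f"2020-{rng.integers(1, 13):02d}", int(rng.integers(1, 20)))
            for _ in range(400)
        ]
        counts = counts_builder(rows)
        counts = (
            counts.groupby(["practice", "code", "month"], as_index=False)["count"].sum()
        )
        members = {"A", "C", "F"}
        out = aggregate_group_counts(counts, self.group("g", sorted(members)))
        brute: dict[tuple, int] = {}
        for _, r in counts.iterrows():
            if r["code"] in members:
                key = (r["practice"], r["month"])
                brute[key] = brute.get(key, 0) + r["count"]
        got = {(r["practice"], r["month"]): r["count"] for _, r in out.iterrows()}
        assert got == brute


class TestRates:
    registry = pd.DataFrame({"practice": ["P1", "P2"], "list_size": [2000, 500]})

    def test_rate_per_1000(self, counts_builder):
        counts = counts_builder([("P1", "X", "2020-01", 5)])
        rates = compute_rates(counts, self.registry)
        p1 = rates[(rates["practice"] == "P1")]
        assert p1["rate"].iloc[0] == pytest.approx(2.5)

    def test_zero_fill_covers_every_registry_practice(self, counts_builder):
        counts = counts_builder([("P1", "X", "2020-01", 5)])
        rates = compute_rates(counts, self.registry, window=("2020-01", "2020-03"))
        # dense grid: 2 practices x 1 code x 3 months
        assert len(rates) == 6
        p2 = rates[rates["practice"] == "P2"]
        assert (p2["rate"] == 0.0).all()

    def test_unregistered_practice_is_named(self, counts_builder):
        counts = counts_builder([("P9", "X", "2020-01", 1)])
        with pytest.raises(KeyError, match="P9"):
            compute_rates(counts, self.registry)

    def test_bad_list_size_rejected(self, counts_builder):
        counts = counts_builder([("P1", "X", "2020-01", 1)])
        bad = pd.DataFrame({"practice": ["P1"], "list_size": [0]})
        with pytest.raises(ValueError, match="list_size"):
            compute_rates(counts, bad)

    def test_elementwise_oracle(self, counts_builder):
        rng = np.random.default_rng(8)
        registry = pd.DataFrame(
            {
                "practice": [f"P{i}" for i in range(6)],
                "list_size": rng.integers(1000, 20000, 6),
            }
        )
        rows = [
            (f"P{rng.integers(6)}", rng.choice(list("AB")),
             f"2020-{rng.integers(1, 4):02d}", int(rng.integers(0, 50)))
            for _ in range(60)
        ]
        counts = counts_builder(rows)
        counts = (
            counts.groupby(["practice", "code", "month"], as_index=False)["count"].sum()
        )
        rates = compute_rates(counts, registry)
        sizes = registry.set_index("practice")["list_size"]
        lookup = counts.set_index(["practice", "code", "month"])["count"]
        for _, r in rates.iterrows():
            key = (r["practice"], r["code"], r["month"])
            n = lookup.get(key, 0)
            assert r["rate"] == pytest.approx(1000 * n / sizes[r["practice"]])

    def test_homogeneity(self, counts_builder):
        counts = counts_builder(
            [("P1", "X", "2020-01", 4), ("P2", "X", "2020-01", 10)]
        )
        base = compute_rates(counts, self.registry)
        doubled = counts.assign(count=counts["count"] * 2)
        assert np.allclose(
            compute_rates(doubled, self.registry)["rate"], base["rate"] * 2
        )
        big_reg = self.registry.assign(list_size=self.registry["list_size"] * 2)
        assert np.allclose(
            compute_rates(counts, big_reg)["rate"], base["rate"] / 2
        )


def test_partition_conservation(counts_builder):
    """Disjoint group counts sum exactly to the per-practice-month totals."""
    rng = np.random.default_rng(21)
    codes = list("ABCDEFGH")
    rows = [
        (f"P{rng.integers(4)}", rng.choice(codes),
         f"2019-{rng.integers(1, 13):02d}", int(rng.integers(1, 9)))
        for _ in range(300)
    ]
    counts = counts_builder(rows)
    counts = counts.groupby(["practice", "code", "month"], as_index=False)["count"].sum()
    h = CodeHierarchy([ClinicalCode(c, c, None) for c in codes])
    parts = [("g1", ("A", "B", "C")), ("g2", ("D", "E")), ("g3", ("F", "G", "H"))]
    pieces = [
        aggregate_group_counts(counts, build_group(h, GroupDefinition(n, members=m)))
        for n, m in parts
    ]
    summed = (
        pd.concat(pieces)
        .groupby(["practice", "month"], as_index=False)["count"].sum()
    )
    totals = counts.groupby(["practice", "month"], as_index=False)["count"].sum()
    assert summed.sort_values(["practice", "month"]).reset_index(drop=True).equals(
        totals.sort_values(["practice", "month"]).reset_index(drop=True)
    )


def test_total_counts_series(counts_builder):
    counts = counts_builder(
        [("P1", "X", "2020-01", 1), ("P1", "X", "2020-02", 2),
         ("P2", "X", "2020-02", 3)]
    )
    totals = total_counts(counts, "X")
    assert totals.tolist() == [1, 5]
    with pytest.raises(KeyError):
        total_counts(counts, "nope")
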
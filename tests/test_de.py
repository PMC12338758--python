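"""Differential-expression thresholding, binning, overlap and exports."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from annotweave.de import (
    DEError,
    DERecord,
    filter_significant,
    fold_bin_summary,
    load_de_table,
    overlap_sets,
    ranked_export,
    split_enrichment_directions,
    top_table,
    venn3_partition,
    volcano_prep,
)
from annotweave.fixtures import DEPlant, DayPlant, make_de_table


def rec(gid, lfc, padj, bm=500.0):
    return DERecord(gene_id=gid, base_mean=bm, log2fc=lfc, padj=padj)


class TestFilter:
    def test_clear_pass_goes_up(self):
        up, down = filter_significant([rec("a", 1.0, 0.05)])
        assert up == {"a"} and down == frozenset()

    def test_boundaries_are_strict(self):
        records = [
            rec("at_lfc", 0.6, 0.05),     # |lfc| not > 0.6
            rec("at_padj", 1.0, 0.1),     # padj not < 0.1
            rec("down", -0.61, 0.099),
        ]
        up, down = filter_significant(records)
        assert up == frozenset() and down == {"down"}

    def test_absent_padj_excluded(self):
        up, down = filter_significant([rec("na", 5.0, None)])
        assert up == frozenset() and down == frozenset()

    @settings(deadline=None, derandomize=True)
    @given(
        lfcs=st.lists(st.floats(-6, 6, allow_nan=False), min_size=1,
                      max_size=40),
        padj_max=st.floats(0.01, 0.5),
        lfc_min=st.floats(0.1, 3),
    )
    def test_relaxing_thresholds_is_monotone(self, lfcs, padj_max, lfc_min):
        records = [
            rec(f"g{i}", lfc, round(abs(lfc) % 1, 6)) for i, lfc in enumerate(lfcs)
        ]
        up1, down1 = filter_significant(records, padj_max, lfc_min)
        up2, down2 = filter_significant(records, padj_max + 0.1, lfc_min)
        up3, down3 = filter_significant(records, padj_max, lfc_min / 2)
        assert up1 <= up2 and down1 <= down2
        assert up1 <= up3 and down1 <= down3


class TestFoldBins:
    def test_four_fold_is_inclusive_at_log2fc_two(self):
        records = [rec("a", 2.0, 0.01), rec("b", 1.9, 0.01),
                   rec("c", -2.0, 0.01)]
        up, down = filter_significant(records)
        s = fold_bin_summary(up, down, records)
        assert s.up_ge4fold == 1 and s.down_ge4fold == 1

    def test_empty_sets_give_zeros(self):
        s = fold_bin_summary(frozenset(), frozenset(), [])
        assert s.up_ge4fold == 0 and s.down_ge4fold == 0

    def test_planted_day_tables_reproduce_printed_ratios(self):
        """Each timepoint's >= 4-fold shares match the printed summaries:
        day1 75/263 (29%) up and 14/173 (8%) down, day3 131/218 (60%) and
        22/71 (31%), day7 15/24 (62.5%) and 13/14 (93%)."""
        fix = make_de_table(DEPlant(seed=7))
        expected = {
            "d1": (75, "29%", 14, "8%"),
            "d3": (131, "60%", 22, "31%"),
            "d7": (15, "62.5%", 13, "93%"),
        }
        for day, (n_up4, pct_up, n_down4, pct_down) in expected.items():
            records = load_de_table(fix.tables[day])
            up, down = filter_significant(records)
            s = fold_bin_summary(up, down, records, day=day)
            assert (s.up_ge4fold, s.up_ge4fold_percent) == (n_up4, pct_up)
            assert (s.down_ge4fold, s.down_ge4fold_percent) == (n_down4, pct_down)

    def test_bins_match_independent_scan(self):
        fix = make_de_table(DEPlant(seed=3))
        records = load_de_table(fix.tables["d1"])
        up, down = filter_significant(records)
        s = fold_bin_summary(up, down, records)
        lfc = {r.gene_id: r.log2fc for r in records}
        assert s.up_ge4fold == sum(1 for g in up if lfc[g] >= 2)
        assert s.down_ge4fold == sum(1 for g in down if lfc[g] <= -2)


class TestOverlap:
    def test_disjoint_sets_have_empty_intersections(self):
        p = venn3_partition(frozenset("ab"), frozenset("cd"), frozenset("ef"))
        assert p["d1_d3"] == p["d1_d7"] == p["d3_d7"] == p["d1_d3_d7"] == 0
        assert p["d1_only"] == p["d3_only"] == p["d7_only"] == 2

    def test_hand_enumerable_partition(self):
        p = venn3_partition(
            frozenset("abc"), frozenset("bcd"), frozenset("c")
        )
        assert p == {
            "d1_only": 1, "d3_only": 1, "d7_only": 0,
            "d1_d3": 1, "d1_d7": 0, "d3_d7": 0, "d1_d3_d7": 1,
        }

    def test_regions_partition_the_union(self):
        a, b, c = frozenset("abcdef"), frozenset("defgh"), frozenset("fhij")
        p = venn3_partition(a, b, c)
        assert sum(p.values()) == len(a | b | c)

    def test_planted_overlap_structure_recovered(self):
        """13 genes shared d1∩d3 only, 3 across all days, 1 d1∩d7 and 5
        d3∩d7 among up sets; down sets share nothing."""
        fix = make_de_table(DEPlant(seed=5))
        sums = {}
        for day, text in fix.tables.items():
            records = load_de_table(text)
            up, down = filter_significant(records)
            sums[day] = fold_bin_summary(up, down, records, day=day)
        table = overlap_sets(sums["d1"], sums["d3"], sums["d7"])
        assert table.up_regions["d1_d3"] == 13
        assert table.up_regions["d1_d3_d7"] == 3
        assert table.up_regions["d1_d7"] == 1
        assert table.up_regions["d3_d7"] == 5
        assert all(
            table.down_regions[k] == 0
            for k in ("d1_d3", "d1_d7", "d3_d7", "d1_d3_d7")
        )


class TestTopTable:
    RECORDS = [
        rec("hi_up", 6.0, 0.01, bm=500),
        rec("lo_up", 1.0, 0.01, bm=500),
        rec("faint_up", 8.0, 0.01, bm=30),     # below baseMean floor
        rec("dn1", -3.0, 0.01, bm=200),
        rec("tie_a", 2.5, 0.01, bm=100),
        rec("tie_b", 2.5, 0.01, bm=100),
        rec("ns", 9.0, 0.5, bm=900),
    ]

    def test_no_padding_beyond_available(self):
        ups, downs = top_table(self.RECORDS, n=10)
        assert len(ups) == 4 and len(downs) == 1

    def test_low_expression_filtered_and_order_by_fold(self):
        ups, _ = top_table(self.RECORDS, n=10)
        assert [e.gene_id for e in ups] == ["hi_up", "tie_a", "tie_b", "lo_up"]

    def test_tie_breaks_lexicographically(self):
        ups, _ = top_table(self.RECORDS, n=3)
        assert [e.gene_id for e in ups][1:] == ["tie_a", "tie_b"]

    def test_nss_label_from_evalue_threshold(self):
        notes = {"hi_up": ("Vitellogenin-1", 1e-30),
                 "tie_a": ("weak hit", 1e-5)}
        ups, _ = top_table(self.RECORDS, n=3, annotations=notes)
        by_id = {e.gene_id: e.description for e in ups}
        assert by_id["hi_up"] == "Vitellogenin-1"
        assert by_id["tie_a"] == "NSS"          # E-value above 1e-10
        assert by_id["tie_b"] == "NSS"          # no hit at all


class TestVolcano:
    def test_pvalues_clamped_at_floor(self):
        (row,) = volcano_prep([rec("a", 3.0, 1e-30)])
        assert row.neg_log10_padj == pytest.approx(10.0)

    def test_neutral_gene_is_ns(self):
        (row,) = volcano_prep([rec("a", 0.0, 0.5)])
        assert row.category == "ns"

    def test_categories_match_independent_predicates(self):
        fix = make_de_table(DEPlant(seed=9))
        records = load_de_table(fix.tables["d3"])
        rows = volcano_prep(records)
        for row in rows:
            r = next(x for x in records if x.gene_id == row.gene_id
                     and x.log2fc == row.log2fc)
            sig_p = r.padj < 0.1
            sig_fc = abs(r.log2fc) > 0.6
            want = ("significant" if sig_p and sig_fc else
                    "p_only" if sig_p else "fc_only" if sig_fc else "ns")
            assert row.category == want
        up, down = filter_significant(records)
        n_sig = sum(1 for r in rows if r.category == "significant")
        assert n_sig == len(up) + len(down)


class TestRankedExport:
    def test_all_below_floor_gives_empty_export(self):
        assert ranked_export([rec("a", 1.0, 0.1, bm=50)]) == []

    def test_row_count_equals_floor_pass(self):
        records = [rec(f"g{i}", float(i), 0.5, bm=50 + 20 * i)
                   for i in range(10)]
        rows = ranked_export(records)
        assert len(rows) == sum(1 for r in records if r.base_mean >= 100)

    def test_sorted_descending_with_lexicographic_ties(self):
        records = [rec("b", 1.0, 0.5), rec("a", 1.0, 0.5), rec("c", 3.0, 0.5)]
        assert ranked_export(records) == [("c", 3.0), ("a", 1.0), ("b", 1.0)]


class TestSplitDirections:
    def test_both_rows_folded_into_each_list(self):
        rows = [{"term": "A", "direction": "up"},
                {"term": "B", "direction": "both"},
                {"term": "C", "direction": "down"}]
        up, down = split_enrichment_directions(rows)
        assert [r["term"] for r in up] == ["A", "B"]
        assert [r["term"] for r in down] == ["B", "C"]

    def test_counting_identity(self):
        rows = (
            [{"direction": "up"}] * 6 + [{"direction": "down"}] * 9
            + [{"direction": "both"}] * 5
        )
        up, down = split_enrichment_directions(rows)
        assert len(up) + len(down) == 6 + 9 + 2 * 5

    def test_unknown_direction_rejected(self):
        with pytest.raises(DEError):
            split_enrichment_directions([{"direction": "sideways"}])
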
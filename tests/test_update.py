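"""Update planning, application, id assignment and merge accounting."""

import pytest

from annotweave.compare import ClassCode, ComparisonResult, classify_all
from annotweave.fixtures import TruthLog
from annotweave.update import (
    UpdateError,
    apply_updates,
    assign_gene_id,
    merge_distribution_table,
    plan_updates,
)

from helpers import annotation, tx


def _exact(tid, gene, ref_tid):
    return ComparisonResult(tid, ClassCode.EXACT, (gene,), ref_tid)


class TestPlan:
    def test_all_exact_plans_nothing(self):
        ref = annotation([tx("g1.t1", "g1", [(100, 200), (300, 400)])])
        ev = annotation(
            [tx("e1", "s1", [(100, 200), (300, 400)])], provenance="evidence"
        )
        plan = plan_updates([_exact("e1", "g1", "g1.t1")], ref, ev)
        assert plan.actions == []
        assert plan.discarded_transcript_ids == ("e1",)

    def test_chained_spans_close_transitively(self):
        """tA joins {g1,g2} and tB joins {g2,g3}: union-find closure must
        produce a single merge of all three genes."""
        ref = annotation(
            [
                tx("g1.t1", "g1", [(1000, 1400)]),
                tx("g2.t1", "g2", [(5000, 5400)]),
                tx("g3.t1", "g3", [(9000, 9400)]),
            ]
        )
        ev = annotation(
            [
                tx("tA", "s1", [(1300, 1400), (5000, 5100)]),
                tx("tB", "s2", [(5300, 5400), (9000, 9100)]),
            ],
            provenance="evidence",
        )
        comparisons = [
            ComparisonResult("tA", ClassCode.SPANS_MULTIPLE, ("g1", "g2")),
            ComparisonResult("tB", ClassCode.SPANS_MULTIPLE, ("g2", "g3")),
        ]
        plan = plan_updates(comparisons, ref, ev)
        merges = [a for a in plan.actions if a.kind == "MERGE"]
        assert len(merges) == 1
        assert merges[0].target_gene_ids == ("g1", "g2", "g3")
        assert merges[0].evidence_transcript_ids == ("tA", "tB")

    def test_unknown_reference_gene_rejected(self):
        ref = annotation([tx("g1.t1", "g1", [(100, 200)])])
        ev = annotation([tx("e1", "s1", [(100, 200)])], provenance="evidence")
        bad = [ComparisonResult("e1", ClassCode.EXONIC_OVERLAP_ONLY, ("gX",))]
        with pytest.raises(UpdateError, match="gX"):
            plan_updates(bad, ref, ev)

    def test_short_single_exon_intergenic_discarded(self):
        ref = annotation([tx("g1.t1", "g1", [(100, 200)])])
        ev = annotation(
            [
                tx("short", "s1", [(50_000, 50_149)]),   # 150 nt < 200
                tx("long", "s2", [(90_000, 90_399)]),    # 400 nt
            ],
            provenance="evidence",
        )
        comparisons = [
            ComparisonResult("short", ClassCode.INTERGENIC),
            ComparisonResult("long", ClassCode.INTERGENIC),
        ]
        plan = plan_updates(comparisons, ref, ev)
        kinds = [a.kind for a in plan.actions]
        assert kinds == ["NEW_GENE"]
        assert plan.actions[0].evidence_transcript_ids == ("long",)
        assert "short" in plan.discarded_transcript_ids

    def test_fixture_plan_equals_planted_truth(self, default_scenario):
        reference, evidence, truth = default_scenario
        plan = plan_updates(
            classify_all(evidence, reference), reference, evidence
        )
        assert TruthLog.plan_action_set(plan) == truth.action_set()
        assert set(plan.discarded_transcript_ids) == truth.discarded

    def test_large_merge_group_representable(self):
        """An eleven-gene chain must close into a single k=11 merge."""
        from annotweave.fixtures import ScenarioSpec, make_annotation_pair

        spec = ScenarioSpec(seed=2, n_ref_genes=15, n_exact=0,
                            n_novel_isoforms=0, merge_groups=(11,),
                            n_novel_genes=0, n_opposite_strand=0,
                            n_intergenic_discard=0)
        ref, ev, truth = make_annotation_pair(spec)
        plan = plan_updates(classify_all(ev, ref), ref, ev)
        merges = [a for a in plan.actions if a.kind == "MERGE"]
        assert len(merges) == 1 and len(merges[0].target_gene_ids) == 11


class TestApply:
    def test_empty_plan_is_identity(self, default_scenario):
        reference, evidence, _ = default_scenario
        from annotweave.update import UpdatePlan

        updated, report = apply_updates(
            reference, evidence, UpdatePlan(actions=[], id_counter_start=0)
        )
        assert updated == reference
        assert report.n_isoforms_added == 0
        assert report.merge_distribution == {}
        assert report.n_novel_genes == 0

    def test_merge_keeps_subunit_transcript_ids(self):
        ref = annotation(
            [
                tx("g1.t1", "g1", [(1000, 1400)],
                   attributes={}),
                tx("g2.t1", "g2", [(5000, 5400)]),
            ]
        )
        ev = annotation(
            [tx("join1", "s1", [(1300, 1400), (5000, 5100)])],
            provenance="evidence",
        )
        comparisons = [
            ComparisonResult("join1", ClassCode.SPANS_MULTIPLE, ("g1", "g2"))
        ]
        plan = plan_updates(comparisons, ref, ev)
        updated, report = apply_updates(ref, ev, plan)
        assert updated.n_genes == 1
        (gene,) = updated.genes.values()
        ids = {t.transcript_id for t in gene.transcripts}
        assert {"g1.t1", "g2.t1"} <= ids
        assert len(ids) == 3  # plus the renamed joining isoform
        assert report.merge_distribution == {2: 1}

    def test_merged_gene_annotation_text_concatenated(self):
        from annotweave.models import GeneModel

        g1 = GeneModel("g1", (tx("g1.t1", "g1", [(1000, 1400)]),),
                       {"description": "first"})
        g2 = GeneModel("g2", (tx("g2.t1", "g2", [(5000, 5400)]),),
                       {"description": "second"})
        from annotweave.models import AnnotationSet

        ref = AnnotationSet([g1, g2])
        ev = annotation(
            [tx("join1", "s1", [(1300, 1400), (5000, 5100)])],
            provenance="evidence",
        )
        plan = plan_updates(
            [ComparisonResult("join1", ClassCode.SPANS_MULTIPLE, ("g1", "g2"))],
            ref, ev,
        )
        updated, _ = apply_updates(ref, ev, plan)
        (gene,) = updated.genes.values()
        assert gene.attributes["description"] == "first;second"

    def test_added_isoform_renamed_into_gene_namespace(self):
        ref = annotation(
            [tx("g1.t1", "g1", [(1000, 1100), (1500, 1600), (2000, 2100)])]
        )
        ev = annotation(
            [tx("STRG.1.1", "STRG.1", [(1500, 1600), (2000, 2100)])],
            provenance="evidence",
        )
        plan = plan_updates(
            [ComparisonResult("STRG.1.1", ClassCode.NOVEL_ISOFORM, ("g1",))],
            ref, ev,
        )
        updated, report = apply_updates(ref, ev, plan)
        ids = sorted(t.transcript_id for t in updated.genes["g1"].transcripts)
        assert ids == ["g1.t1", "g1.t2"]
        assert report.n_isoforms_added == 1
        assert report.n_genes_gaining_isoforms == 1

    def test_gene_count_conservation_law(self, default_scenario):
        reference, evidence, _ = default_scenario
        plan = plan_updates(
            classify_all(evidence, reference), reference, evidence
        )
        updated, report = apply_updates(reference, evidence, plan)
        lost = sum((k - 1) * n for k, n in report.merge_distribution.items())
        assert updated.n_genes == \
            reference.n_genes - lost + report.n_novel_genes

    def test_reference_transcripts_conserved(self, default_scenario):
        reference, evidence, _ = default_scenario
        plan = plan_updates(
            classify_all(evidence, reference), reference, evidence
        )
        updated, _ = apply_updates(reference, evidence, plan)
        ref_ids = set(reference.transcript_to_gene())
        out_ids = list(updated.transcript_to_gene())
        assert ref_ids <= set(out_ids)
        assert len(out_ids) == len(set(out_ids))

    def test_untouched_gene_attributes_byte_identical(self, default_scenario):
        reference, evidence, _ = default_scenario
        plan = plan_updates(
            classify_all(evidence, reference), reference, evidence
        )
        updated, _ = apply_updates(reference, evidence, plan)
        touched = {g for a in plan.actions for g in a.target_gene_ids}
        for gid, gene in reference.genes.items():
            if gid not in touched:
                assert updated.genes[gid].attributes == gene.attributes

    def test_rerun_with_updated_reference_plans_nothing(self, default_scenario):
        """Idempotence: the update's own output absorbs all its evidence."""
        reference, evidence, _ = default_scenario
        plan = plan_updates(
            classify_all(evidence, reference), reference, evidence
        )
        updated, _ = apply_updates(reference, evidence, plan)
        plan2 = plan_updates(
            classify_all(evidence, updated), updated, evidence
        )
        assert plan2.actions == []


class TestGeneIds:
    def test_formatting_and_bounds(self):
        assert assign_gene_id(14732) == "GBIG_014732"
        assert assign_gene_id(0) == "GBIG_000000"
        with pytest.raises(ValueError):
            assign_gene_id(1_000_000)
        with pytest.raises(ValueError):
            assign_gene_id(-1)

    def test_sequential_ids_distinct_and_ordered(self):
        ids = [assign_gene_id(i) for i in range(1000)]
        assert len(set(ids)) == 1000
        assert ids == sorted(ids)


class TestMergeTable:
    def test_published_distribution_totals(self):
        dist = {2: 1082, 3: 233, 4: 53, 5: 27, 6: 9, 7: 4, 11: 1}
        table = merge_distribution_table(dist)
        assert table.total == 1409
        assert table.rows[0] == (2, 1082)
        assert table.rows[-1] == (11, 1)

    def test_empty_distribution(self):
        table = merge_distribution_table({})
        assert table.rows == () and table.total == 0

    def test_table_matches_recount_over_plan(self, default_scenario):
        reference, evidence, _ = default_scenario
        plan = plan_updates(
            classify_all(evidence, reference), reference, evidence
        )
        _, report = apply_updates(reference, evidence, plan)
        table = merge_distribution_table(report)
        recount = {}
        for a in plan.actions:
            if a.kind == "MERGE":
                k = len(a.target_gene_ids)
                recount[k] = recount.get(k, 0) + 1
        assert dict(table.rows) == recount
        assert table.total == sum(recount.values())

    def test_sub_two_merge_size_rejected(self):
        with pytest.raises(UpdateError):
            merge_distribution_table({1: 5})
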
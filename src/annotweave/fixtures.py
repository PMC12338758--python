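"""Deterministic synthetic fixtures with ground-truth logs.

Everything the pipeline consumes — reference/evidence GTF pairs, BUSCO
full tables, differential-expression result tables — can be generated
here with a planted truth that suffices to verify each downstream
module exactly.  Generation is a pure function of its spec: the same
seed always yields byte-identical text.

The annotation generator lays reference genes left to right on a
synthetic scaffold with inter-gene gaps larger than any intron, then
constructs evidence transcripts class by class: exact copies (with
perturbed terminal exon ends), novel isoforms (a reference chain with
its first exon dropped), chains of pairwise gene-spanning transcripts
realising planted merge groups, intergenic clusters destined to become
novel genes, antisense overlaps, and sub-length single-exon fragments
that the update step must discard.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .models import (
    AnnotationSet,
    GenomicInterval,
    GeneModel,
    TranscriptModel,
)
from .update import UpdatePlan

TABLE2_FULL_DISTRIBUTION: Dict[int, int] = {
    2: 1082, 3: 233, 4: 53, 5: 27, 6: 9, 7: 4, 11: 1,
}


class FixtureError(ValueError):
    """The requested scenario is internally infeasible."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Planted composition of a reference/evidence annotation pair."""

    seed: int = 0
    n_ref_genes: int = 30
    n_exact: int = 5
    n_novel_isoforms: int = 6
    merge_groups: Tuple[int, ...] = (2, 3)
    n_novel_genes: int = 3
    n_opposite_strand: int = 2
    n_intergenic_discard: int = 2
    exon_count_range: Tuple[int, int] = (3, 5)
    exon_len_range: Tuple[int, int] = (100, 400)
    intron_len_range: Tuple[int, int] = (60, 300)
    min_novel_single_exon_len: int = 200
    scaffold: str = "Scaffold1"

    def __post_init__(self) -> None:
        counts = (
            self.n_ref_genes, self.n_exact, self.n_novel_isoforms,
            self.n_novel_genes, self.n_opposite_strand,
            self.n_intergenic_discard,
        )
        if any(c < 0 for c in counts):
            raise FixtureError("all scenario counts must be >= 0")
        for k in self.merge_groups:
            if k < 2:
                raise FixtureError(f"merge group of size {k} is not a merge")
            if k > self.n_ref_genes:
                raise FixtureError(
                    f"merge group of {k} genes exceeds n_ref_genes="
                    f"{self.n_ref_genes}"
                )
        if self.required_ref_genes > self.n_ref_genes:
            raise FixtureError(
                f"scenario needs {self.required_ref_genes} reference genes "
                f"for its planted classes but n_ref_genes={self.n_ref_genes}"
            )
        if self.exon_len_range[0] < 100:
            raise FixtureError("exon lengths below 100 break spanning exons")

    @property
    def required_ref_genes(self) -> int:
        return (
            sum(self.merge_groups) + self.n_novel_isoforms
            + self.n_opposite_strand + self.n_exact
        )


@dataclass(frozen=True)
class PlannedAction:
    kind: str
    target_gene_ids: Tuple[str, ...]
    evidence_transcript_ids: Tuple[str, ...]


@dataclass
class TruthLog:
    """What was planted: one class code per evidence transcript plus the
    update actions the planner is expected to recover."""

    codes: Dict[str, str] = field(default_factory=dict)
    actions: List[PlannedAction] = field(default_factory=list)
    discarded: Set[str] = field(default_factory=set)

    @property
    def merge_distribution(self) -> Dict[int, int]:
        dist: Dict[int, int] = {}
        for a in self.actions:
            if a.kind == "MERGE":
                k = len(a.target_gene_ids)
                dist[k] = dist.get(k, 0) + 1
        return dist

    @property
    def n_novel_genes(self) -> int:
        return sum(1 for a in self.actions if a.kind == "NEW_GENE")

    @property
    def n_isoforms_added(self) -> int:
        return sum(
            len(a.evidence_transcript_ids)
            for a in self.actions
            if a.kind == "ADD_ISOFORM"
        )

    def action_set(self) -> Set[Tuple[str, Tuple[str, ...], Tuple[str, ...]]]:
        return {
            (a.kind, a.target_gene_ids, tuple(sorted(a.evidence_transcript_ids)))
            for a in self.actions
        }

    @staticmethod
    def plan_action_set(
        plan: UpdatePlan,
    ) -> Set[Tuple[str, Tuple[str, ...], Tuple[str, ...]]]:
        return {
            (a.kind, a.target_gene_ids, tuple(sorted(a.evidence_transcript_ids)))
            for a in plan.actions
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "codes": self.codes,
                "actions": [
                    {
                        "kind": a.kind,
                        "target_gene_ids": list(a.target_gene_ids),
                        "evidence_transcript_ids": list(
                            a.evidence_transcript_ids
                        ),
                    }
                    for a in self.actions
                ],
                "discarded": sorted(self.discarded),
            },
            indent=2,
        )


def _build_exons(
    rng: random.Random,
    cursor: int,
    n_exons: int,
    exon_len_range: Tuple[int, int],
    intron_len_range: Tuple[int, int],
    seqid: str,
    strand: str,
) -> Tuple[Tuple[GenomicInterval, ...], int]:
    exons = []
    pos = cursor
    for i in range(n_exons):
        length = rng.randint(*exon_len_range)
        exons.append(
            GenomicInterval(seqid=seqid, start=pos, end=pos + length - 1,
                            strand=strand)
        )
        pos += length
        if i < n_exons - 1:
            pos += rng.randint(*intron_len_range)
    return tuple(exons), pos


def make_annotation_pair(
    spec: ScenarioSpec,
) -> Tuple[AnnotationSet, AnnotationSet, TruthLog]:
    """Generate a (reference, evidence, truth) triple for a scenario."""
    rng = random.Random(spec.seed)
    gap = spec.intron_len_range[1] + 500
    seqid = spec.scaffold
    truth = TruthLog()

    # contiguous gene-index pools, merge groups first so each group is a
    # run of consecutive neighbors on the scaffold
    roles: List[Tuple[str, int]] = []  # (role, group index)
    for gi, k in enumerate(spec.merge_groups):
        roles += [("merge", gi)] * k
    roles += [("novel_isoform", i) for i in range(spec.n_novel_isoforms)]
    roles += [("opposite", i) for i in range(spec.n_opposite_strand)]
    roles += [("exact", i) for i in range(spec.n_exact)]
    roles += [("untouched", 0)] * (spec.n_ref_genes - len(roles))

    cursor = 1000
    ref_genes: List[GeneModel] = []
    gene_role: List[Tuple[str, str, int]] = []  # (gene_id, role, group)
    first_tx: Dict[str, TranscriptModel] = {}
    for i, (role, group) in enumerate(roles):
        gid = f"GBI_{i:05d}"
        n_exons = rng.randint(*spec.exon_count_range)
        if role == "novel_isoform":
            n_exons = max(3, n_exons)
        if role == "opposite":
            n_exons = max(2, n_exons)
        exons, cursor = _build_exons(
            rng, cursor, n_exons, spec.exon_len_range,
            spec.intron_len_range, seqid, "+",
        )
        t1 = TranscriptModel(
            transcript_id=f"{gid}.t1", gene_id=gid, exons=exons
        )
        txs = [t1]
        if role == "untouched" and n_exons >= 3 and rng.random() < 0.25:
            drop = rng.randrange(1, n_exons - 1)
            txs.append(
                TranscriptModel(
                    transcript_id=f"{gid}.t2",
                    gene_id=gid,
                    exons=tuple(e for j, e in enumerate(exons) if j != drop),
                )
            )
        ref_genes.append(
            GeneModel(
                gene_id=gid,
                transcripts=tuple(txs),
                attributes={"description": f"Similar to protein {i}"},
            )
        )
        gene_role.append((gid, role, group))
        first_tx[gid] = t1
        cursor += gap + rng.randint(0, 200)

    reference = AnnotationSet(ref_genes, provenance="reference")

    # evidence transcripts, grouped into StringTie-style evidence genes
    ev_gene_counter = 0
    ev_genes: List[GeneModel] = []

    def new_evidence_gene(
        tx_exons: Sequence[Tuple[GenomicInterval, ...]],
    ) -> List[str]:
        nonlocal ev_gene_counter
        ev_gene_counter += 1
        ev_gid = f"STRG.{ev_gene_counter}"
        txs = []
        ids = []
        for j, exons in enumerate(tx_exons, start=1):
            tid = f"{ev_gid}.{j}"
            txs.append(
                TranscriptModel(transcript_id=tid, gene_id=ev_gid, exons=exons)
            )
            ids.append(tid)
        ev_genes.append(GeneModel(gene_id=ev_gid, transcripts=tuple(txs)))
        return ids

    # exact copies, terminal exon ends perturbed for multi-exon donors
    for gid, role, _ in gene_role:
        if role != "exact":
            continue
        donor = first_tx[gid]
        exons = list(donor.exons)
        if donor.is_multi_exon:
            first, last = exons[0], exons[-1]
            exons[0] = GenomicInterval(
                first.seqid, max(1, first.start - rng.randint(1, 50)),
                first.end, first.strand,
            )
            exons[-1] = GenomicInterval(
                last.seqid, last.start, last.end + rng.randint(1, 50),
                last.strand,
            )
        (tid,) = new_evidence_gene([tuple(exons)])
        truth.codes[tid] = "EXACT"
        truth.discarded.add(tid)

    # novel isoforms: the donor chain with its first exon dropped
    for gid, role, _ in gene_role:
        if role != "novel_isoform":
            continue
        donor = first_tx[gid]
        (tid,) = new_evidence_gene([donor.exons[1:]])
        truth.codes[tid] = "NOVEL_ISOFORM"
        truth.actions.append(
            PlannedAction(
                kind="ADD_ISOFORM",
                target_gene_ids=(gid,),
                evidence_transcript_ids=(tid,),
            )
        )

    # merge groups: k-1 chained transcripts, each spanning one neighbor pair
    merge_members: Dict[int, List[str]] = {}
    for gid, role, group in gene_role:
        if role == "merge":
            merge_members.setdefault(group, []).append(gid)
    for group in sorted(merge_members):
        members = merge_members[group]
        joiner_ids = []
        for ga, gb in zip(members, members[1:]):
            left = first_tx[ga].exons[-1]
            right = first_tx[gb].exons[0]
            exon_a = GenomicInterval(seqid, left.end - 79, left.end, "+")
            exon_b = GenomicInterval(seqid, right.start, right.start + 79, "+")
            (tid,) = new_evidence_gene([(exon_a, exon_b)])
            truth.codes[tid] = "SPANS_MULTIPLE"
            joiner_ids.append(tid)
        truth.actions.append(
            PlannedAction(
                kind="MERGE",
                target_gene_ids=tuple(members),
                evidence_transcript_ids=tuple(joiner_ids),
            )
        )

    # antisense overlaps: two exons inside donor exons, flipped strand
    for gid, role, _ in gene_role:
        if role != "opposite":
            continue
        donor = first_tx[gid]
        e0, e1 = donor.exons[0], donor.exons[1]
        exons = (
            GenomicInterval(seqid, e0.start, e0.start + 79, "-"),
            GenomicInterval(seqid, e1.start, e1.start + 79, "-"),
        )
        (tid,) = new_evidence_gene([exons])
        truth.codes[tid] = "OPPOSITE_STRAND"
        truth.discarded.add(tid)

    # novel gene clusters in intergenic space beyond the last gene
    cursor += 4 * gap
    for _ in range(spec.n_novel_genes):
        n_exons = max(2, rng.randint(*spec.exon_count_range) - 1)
        exons, cursor = _build_exons(
            rng, cursor, n_exons, spec.exon_len_range,
            spec.intron_len_range, seqid, "+",
        )
        members = [tuple(exons)]
        if rng.random() < 0.5:
            first, last = exons[0], exons[-1]
            shrunk = list(exons)
            shrunk[0] = GenomicInterval(
                seqid, first.start + 10, first.end, "+"
            )
            shrunk[-1] = GenomicInterval(seqid, last.start, last.end - 10, "+")
            members.append(tuple(shrunk))
        ids = new_evidence_gene(members)
        for tid in ids:
            truth.codes[tid] = "INTERGENIC"
        truth.actions.append(
            PlannedAction(
                kind="NEW_GENE",
                target_gene_ids=(),
                evidence_transcript_ids=tuple(sorted(ids)),
            )
        )
        cursor += gap

    # sub-length single-exon fragments: intergenic, planned as discards
    for _ in range(spec.n_intergenic_discard):
        length = rng.randint(50, spec.min_novel_single_exon_len - 50)
        exon = GenomicInterval(seqid, cursor, cursor + length - 1, ".")
        (tid,) = new_evidence_gene([(exon,)])
        truth.codes[tid] = "INTERGENIC"
        truth.discarded.add(tid)
        cursor += gap

    evidence = AnnotationSet(ev_genes, provenance="evidence")
    return reference, evidence, truth


def table2_scenario(seed: int = 0, scale: int = 50) -> ScenarioSpec:
    """A scenario whose planted merge groups mirror the observed neighbor-
    join distribution, optionally scaled down (each count divided by
    ``scale``, minimum one instance so every k survives)."""
    groups: List[int] = []
    for k in sorted(TABLE2_FULL_DISTRIBUTION):
        count = TABLE2_FULL_DISTRIBUTION[k]
        n = max(1, round(count / scale)) if scale > 1 else count
        groups += [k] * n
    needed = sum(groups) + 10
    return ScenarioSpec(
        seed=seed,
        n_ref_genes=needed + 5,
        n_exact=2,
        n_novel_isoforms=3,
        merge_groups=tuple(groups),
        n_novel_genes=2,
        n_opposite_strand=1,
        n_intergenic_discard=1,
    )


# ---------------------------------------------------------------------------
# BUSCO fixture


@dataclass(frozen=True)
class BuscoPlant:
    """Planted gene-level completeness categories for a BUSCO set."""

    n_single: int = 939
    n_duplicated: int = 58
    n_fragmented: int = 9
    n_missing: int = 7
    seed: int = 0
    isoform_dup_every: int = 5  # every n-th single is an isoform-level duplicate

    @property
    def n_total(self) -> int:
        return (
            self.n_single + self.n_duplicated + self.n_fragmented
            + self.n_missing
        )


@dataclass
class BuscoFixture:
    text: str
    tx_to_gene: Dict[str, str]
    truth: Dict[str, str]  # busco_id -> gene-level category


def make_busco_table(
    plant: BuscoPlant,
    tx_to_gene: Optional[Dict[str, str]] = None,
) -> BuscoFixture:
    """Emit a transcript-mode full_table realising the planted categories.

    A fraction of single-copy orthologs are written as two "Duplicated"
    rows on two isoforms of one gene — the transcript-level artifact
    that gene-level reconciliation must collapse back to single.  When
    no transcript-to-gene map is supplied, a synthetic one is built.
    """
    rng = random.Random(plant.seed)
    synthesize = tx_to_gene is None
    mapping: Dict[str, str] = {} if synthesize else dict(tx_to_gene)
    gene_counter = 0

    def alloc(n_tx: int) -> Tuple[str, List[str]]:
        nonlocal gene_counter
        gene_counter += 1
        gid = f"BG_{gene_counter:05d}"
        tids = [f"{gid}.t{j}" for j in range(1, n_tx + 1)]
        for tid in tids:
            mapping[tid] = gid
        return gid, tids

    if not synthesize:
        by_gene: Dict[str, List[str]] = {}
        for tid, gid in sorted(mapping.items()):
            by_gene.setdefault(gid, []).append(tid)
        gene_pool = sorted(by_gene)
        if len(gene_pool) < 2 * plant.n_duplicated + plant.n_single + \
                plant.n_fragmented:
            raise FixtureError("transcript map has too few genes for plant")
        pool_iter = iter(gene_pool)

        def alloc(n_tx: int) -> Tuple[str, List[str]]:  # noqa: F811
            for gid in pool_iter:
                if len(by_gene[gid]) >= n_tx:
                    return gid, by_gene[gid][:n_tx]
            raise FixtureError(
                f"no remaining gene with >= {n_tx} transcripts in map"
            )

    lines = [
        "# BUSCO version is: 5.7.0",
        "# The lineage dataset is: arthropoda_odb10",
        "# Busco id\tStatus\tSequence\tScore\tLength",
    ]
    truth: Dict[str, str] = {}
    idx = 0

    def busco_id() -> str:
        nonlocal idx
        idx += 1
        return f"{idx:06d}at6656"

    for i in range(plant.n_single):
        bid = busco_id()
        truth[bid] = "complete_single"
        score = round(rng.uniform(200, 900), 1)
        length = rng.randint(300, 3000)
        if plant.isoform_dup_every and i % plant.isoform_dup_every == 0:
            _, tids = alloc(2)
            lines.append(f"{bid}\tDuplicated\t{tids[0]}\t{score}\t{length}")
            lines.append(
                f"{bid}\tDuplicated\t{tids[1]}\t{round(score - 1.5, 1)}\t{length}"
            )
        else:
            _, tids = alloc(1)
            lines.append(f"{bid}\tComplete\t{tids[0]}\t{score}\t{length}")
    for _ in range(plant.n_duplicated):
        bid = busco_id()
        truth[bid] = "complete_duplicated"
        for _copy in range(2):
            _, tids = alloc(1)
            score = round(rng.uniform(200, 900), 1)
            lines.append(
                f"{bid}\tDuplicated\t{tids[0]}\t{score}\t{rng.randint(300, 3000)}"
            )
    for _ in range(plant.n_fragmented):
        bid = busco_id()
        truth[bid] = "fragmented"
        _, tids = alloc(1)
        score = round(rng.uniform(50, 180), 1)
        lines.append(
            f"{bid}\tFragmented\t{tids[0]}\t{score}\t{rng.randint(80, 400)}"
        )
    for _ in range(plant.n_missing):
        bid = busco_id()
        truth[bid] = "missing"
        lines.append(f"{bid}\tMissing")

    return BuscoFixture(
        text="\n".join(lines) + "\n", tx_to_gene=mapping, truth=truth
    )


# ---------------------------------------------------------------------------
# differential-expression fixture


@dataclass(frozen=True)
class DayPlant:
    n_up: int
    n_down: int
    n_up_ge4: int
    n_down_ge4: int

    def __post_init__(self) -> None:
        if self.n_up_ge4 > self.n_up or self.n_down_ge4 > self.n_down:
            raise FixtureError(">= 4-fold subset exceeds significant set")


#: The observed per-timepoint significant-set sizes and 4-fold bins
#: (day: up, down, up >= 4-fold, down >= 4-fold).
DEFAULT_DAY_PLANTS: Dict[str, DayPlant] = {
    "d1": DayPlant(263, 173, 75, 14),
    "d3": DayPlant(218, 71, 131, 22),
    "d7": DayPlant(24, 14, 15, 13),
}

#: Observed cross-timepoint overlap structure of upregulated genes;
#: downregulated sets share nothing.
DEFAULT_UP_OVERLAPS: Dict[Tuple[str, ...], int] = {
    ("d1", "d3"): 13,
    ("d1", "d7"): 1,
    ("d3", "d7"): 5,
    ("d1", "d3", "d7"): 3,
}


@dataclass(frozen=True)
class DEPlant:
    seed: int = 0
    days: Mapping[str, DayPlant] = field(
        default_factory=lambda: dict(DEFAULT_DAY_PLANTS)
    )
    up_overlaps: Mapping[Tuple[str, ...], int] = field(
        default_factory=lambda: dict(DEFAULT_UP_OVERLAPS)
    )
    down_overlaps: Mapping[Tuple[str, ...], int] = field(default_factory=dict)
    n_background: int = 1200
    na_fraction: float = 0.02


@dataclass
class DEFixture:
    tables: Dict[str, str]  # day -> TSV text
    truth: "DETruth"


@dataclass
class DETruth:
    up: Dict[str, Set[str]]
    down: Dict[str, Set[str]]
    up_ge4: Dict[str, Set[str]]
    down_ge4: Dict[str, Set[str]]


def _allocate_sets(
    days: Sequence[str],
    sizes: Mapping[str, int],
    overlaps: Mapping[Tuple[str, ...], int],
    next_id,
) -> Dict[str, Set[str]]:
    sets: Dict[str, Set[str]] = {d: set() for d in days}
    consumed = {d: 0 for d in days}
    for combo, count in sorted(overlaps.items(), key=lambda kv: (-len(kv[0]), kv[0])):
        for d in combo:
            if d not in sets:
                raise FixtureError(f"overlap names unknown day {d!r}")
            consumed[d] += count
        for _ in range(count):
            gid = next_id()
            for d in combo:
                sets[d].add(gid)
    for d in days:
        unique = sizes[d] - consumed[d]
        if unique < 0:
            raise FixtureError(
                f"day {d!r}: overlaps consume {consumed[d]} genes but the "
                f"set only holds {sizes[d]}"
            )
        for _ in range(unique):
            sets[d].add(next_id())
    return sets


def make_de_table(plant: DEPlant) -> DEFixture:
    """Generate per-day DESeq2-style tables realising the planted counts.

    Every planted value sits at least 0.01 away from the significance
    boundaries (padj 0.1, |log2FC| 0.6 and 2.0), so strict-vs-inclusive
    threshold semantics cannot blur the planted truth.  A non-significant
    background is added per day, including baseMean values on both sides
    of the 70 and 100 expression cutoffs and a few NA adjusted p-values.
    """
    rng = random.Random(plant.seed)
    days = sorted(plant.days)
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"G{counter:05d}"

    up_sets = _allocate_sets(
        days, {d: plant.days[d].n_up for d in days}, plant.up_overlaps, next_id
    )
    down_sets = _allocate_sets(
        days, {d: plant.days[d].n_down for d in days}, plant.down_overlaps,
        next_id,
    )
    for d in days:
        if up_sets[d] & down_sets[d]:
            raise FixtureError(f"day {d!r}: up and down sets intersect")
    background = [next_id() for _ in range(plant.n_background)]

    def base_mean() -> float:
        stratum = rng.choice(("low", "mid", "high"))
        if stratum == "low":
            return round(rng.uniform(5, 68), 2)
        if stratum == "mid":
            return round(rng.uniform(72, 98), 2)
        return round(rng.uniform(102, 5000), 2)

    tables: Dict[str, str] = {}
    truth = DETruth(up={}, down={}, up_ge4={}, down_ge4={})
    for d in days:
        day = plant.days[d]
        up = sorted(up_sets[d])
        down = sorted(down_sets[d])
        up_ge4 = set(rng.sample(up, day.n_up_ge4))
        down_ge4 = set(rng.sample(down, day.n_down_ge4))
        rows: List[Tuple[str, float, float, str, str]] = []
        for gid in up:
            lfc = rng.uniform(2.01, 8.0) if gid in up_ge4 \
                else rng.uniform(0.62, 1.98)
            padj = rng.uniform(1e-6, 0.089)
            rows.append(
                (gid, base_mean(), round(lfc, 4),
                 f"{padj * rng.uniform(0.2, 1.0):.3e}", f"{padj:.3e}")
            )
        for gid in down:
            lfc = -rng.uniform(2.01, 8.0) if gid in down_ge4 \
                else -rng.uniform(0.62, 1.98)
            padj = rng.uniform(1e-6, 0.089)
            rows.append(
                (gid, base_mean(), round(lfc, 4),
                 f"{padj * rng.uniform(0.2, 1.0):.3e}", f"{padj:.3e}")
            )
        for gid in background:
            r = rng.random()
            if r < plant.na_fraction:
                rows.append(
                    (gid, base_mean(), round(rng.uniform(-3, 3), 4), "NA", "NA")
                )
            elif r < 0.5:
                # high adjusted p-value, any fold change
                padj = rng.uniform(0.11, 0.95)
                rows.append(
                    (gid, base_mean(), round(rng.uniform(-3, 3), 4),
                     f"{padj * rng.uniform(0.2, 1.0):.3e}", f"{padj:.3e}")
                )
            else:
                # significant p but sub-threshold fold change
                padj = rng.uniform(1e-4, 0.089)
                rows.append(
                    (gid, base_mean(), round(rng.uniform(-0.59, 0.59), 4),
                     f"{padj * rng.uniform(0.2, 1.0):.3e}", f"{padj:.3e}")
                )
        rng.shuffle(rows)
        lines = ["gene_id\tbaseMean\tlog2FoldChange\tpvalue\tpadj"]
        lines += [
            f"{gid}\t{bm}\t{lfc}\t{pv}\t{pa}" for gid, bm, lfc, pv, pa in rows
        ]
        tables[d] = "\n".join(lines) + "\n"
        truth.up[d] = set(up)
        truth.down[d] = set(down)
        truth.up_ge4[d] = up_ge4
        truth.down_ge4[d] = down_ge4
    return DEFixture(tables=tables, truth=truth)
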
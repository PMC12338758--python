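"""Turn comparison results into an annotation update and apply it.

Three kinds of action are planned from the class codes:

* ``ADD_ISOFORM`` — a novel isoform is inserted into its reference gene;
  the gene keeps its identifier and annotation text, the transcript is
  renamed ``<gene_id>.tN``.
* ``MERGE`` — transcripts spanning two or more annotated genes are
  evidence that neighboring loci are parts of one transcription unit.
  Spanning results induce edges between reference genes and the
  connected components of that graph (union-find closure) are merged, so
  chained evidence joins k genes even when no single transcript spans
  all k.  The merged gene receives a fresh identifier (``GBIG_NNNNNN``
  by default) while the subunit transcripts keep their identifiers
  verbatim.
* ``NEW_GENE`` — intergenic transcripts, clustered among themselves by
  same-strand exonic overlap, become novel genes (one per cluster).

Exact matches, exonic-overlap-only, opposite-strand, contained and
short single-exon intergenic transcripts are discarded: the update is
conservative and instantiates nothing the evidence does not positively
support.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Tuple

from intervaltree import IntervalTree

from .compare import ClassCode, ComparisonResult
from .models import (
    AnnotationSet,
    GeneModel,
    GtfValidationError,
    TranscriptModel,
    strands_compatible,
)


class UpdateError(ValueError):
    """Inconsistency between comparisons, plan and annotation sets."""


@dataclass
class UpdateConfig:
    """Tunable thresholds of the update step.

    min_novel_single_exon_len
        Minimum exonic length for a single-exon intergenic transcript to
        seed a novel gene (shorter fragments are treated as assembly
        noise and discarded).
    id_prefix / id_start / id_width
        Scheme for newly assigned gene identifiers; merged and novel
        genes draw from one sequential counter.
    """

    min_novel_single_exon_len: int = 200
    id_prefix: str = "GBIG_"
    id_start: int = 0
    id_width: int = 6


@dataclass(frozen=True)
class UpdateAction:
    kind: str  # ADD_ISOFORM | MERGE | NEW_GENE
    evidence_transcript_ids: Tuple[str, ...]
    target_gene_ids: Tuple[str, ...]
    new_gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == "ADD_ISOFORM" and len(self.target_gene_ids) != 1:
            raise UpdateError("ADD_ISOFORM targets exactly one gene")
        if self.kind == "MERGE" and len(self.target_gene_ids) < 2:
            raise UpdateError("MERGE targets at least two genes")
        if self.kind == "NEW_GENE" and self.target_gene_ids:
            raise UpdateError("NEW_GENE targets no reference gene")
        if self.kind in ("MERGE", "NEW_GENE") and not self.new_gene_id:
            raise UpdateError(f"{self.kind} requires a new_gene_id")


@dataclass
class UpdatePlan:
    actions: List[UpdateAction]
    id_counter_start: int
    discarded_transcript_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen_genes: Set[str] = set()
        seen_tx: Set[str] = set()
        for a in self.actions:
            if a.kind == "MERGE":
                dup = seen_genes & set(a.target_gene_ids)
                if dup:
                    raise UpdateError(
                        f"gene(s) {sorted(dup)} appear in two MERGE actions"
                    )
                seen_genes |= set(a.target_gene_ids)
            for tid in a.evidence_transcript_ids:
                if tid in seen_tx:
                    raise UpdateError(
                        f"evidence transcript {tid!r} appears in two actions"
                    )
                seen_tx.add(tid)


@dataclass(frozen=True)
class UpdateReport:
    n_isoforms_added: int
    n_genes_gaining_isoforms: int
    max_isoforms_added_to_one_gene: int
    merge_distribution: Mapping[int, int]
    n_novel_genes: int
    n_discarded: int

    def to_dict(self) -> dict:
        return {
            "n_isoforms_added": self.n_isoforms_added,
            "n_genes_gaining_isoforms": self.n_genes_gaining_isoforms,
            "max_isoforms_added_to_one_gene": self.max_isoforms_added_to_one_gene,
            "merge_distribution": {
                str(k): v for k, v in sorted(self.merge_distribution.items())
            },
            "n_novel_genes": self.n_novel_genes,
            "n_discarded": self.n_discarded,
        }


def assign_gene_id(counter: int, prefix: str = "GBIG_", width: int = 6) -> str:
    """Sequential zero-padded gene identifier, e.g. 14732 -> GBIG_014732."""
    if counter < 0:
        raise ValueError("counter must be >= 0")
    if counter >= 10 ** width:
        raise ValueError(f"gene id counter exhausted at {counter}")
    return f"{prefix}{counter:0{width}d}"


class _GeneIdAllocator:
    """Monotone id source that never reuses an id present in ``reserved``."""

    def __init__(self, config: UpdateConfig, reserved: Set[str]) -> None:
        self._counter = config.id_start
        self._config = config
        self._reserved = reserved

    def next(self) -> str:
        while True:
            gid = assign_gene_id(
                self._counter, self._config.id_prefix, self._config.id_width
            )
            self._counter += 1
            if gid not in self._reserved:
                self._reserved.add(gid)
                return gid


class _UnionFind:
    def __init__(self) -> None:
        self._parent: Dict[str, str] = {}

    def find(self, x: str) -> str:
        parent = self._parent.setdefault(x, x)
        if parent != x:
            self._parent[x] = parent = self.find(parent)
        return parent

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self._parent[max(ra, rb)] = min(ra, rb)

    def components(self) -> List[List[str]]:
        groups: Dict[str, List[str]] = {}
        for x in self._parent:
            groups.setdefault(self.find(x), []).append(x)
        return [sorted(v) for v in groups.values()]


def _gene_sort_key(reference: AnnotationSet, gene_ids: Iterable[str]):
    starts = [
        (reference.genes[g].seqid, reference.genes[g].start) for g in gene_ids
    ]
    return min(starts)


def plan_updates(
    comparisons: List[ComparisonResult],
    reference: AnnotationSet,
    evidence: AnnotationSet,
    config: Optional[UpdateConfig] = None,
) -> UpdatePlan:
    """Build the update plan from classified evidence transcripts.

    ``evidence`` is needed because intergenic transcripts are clustered
    by their exon coordinates and filtered by exonic length, neither of
    which a :class:`~annotweave.compare.ComparisonResult` carries.
    """
    config = config or UpdateConfig()
    ev_tx = {t.transcript_id: t for g in evidence.genes.values()
             for t in g.transcripts}

    for c in comparisons:
        for gid in c.ref_gene_ids:
            if gid not in reference.genes:
                raise UpdateError(
                    f"comparison for {c.transcript_id!r} references unknown "
                    f"gene {gid!r}"
                )
        if c.transcript_id not in ev_tx:
            raise UpdateError(
                f"comparison for unknown evidence transcript {c.transcript_id!r}"
            )

    actions: List[UpdateAction] = []
    discarded: List[str] = []

    # isoform additions, in comparison order
    for c in comparisons:
        if c.code == ClassCode.NOVEL_ISOFORM:
            actions.append(
                UpdateAction(
                    kind="ADD_ISOFORM",
                    evidence_transcript_ids=(c.transcript_id,),
                    target_gene_ids=(c.ref_gene_ids[0],),
                )
            )
        elif c.code in (
            ClassCode.EXACT,
            ClassCode.CONTAINED,
            ClassCode.EXONIC_OVERLAP_ONLY,
            ClassCode.OPPOSITE_STRAND,
        ):
            discarded.append(c.transcript_id)

    # transitive merge closure over spanning evidence
    uf = _UnionFind()
    spanning: List[ComparisonResult] = []
    for c in comparisons:
        if c.code == ClassCode.SPANS_MULTIPLE:
            spanning.append(c)
            first = c.ref_gene_ids[0]
            for gid in c.ref_gene_ids[1:]:
                uf.union(first, gid)
    merge_actions = []
    for component in uf.components():
        strands = {
            reference.genes[g].strand
            for g in component
            if reference.genes[g].strand != "."
        }
        if len(strands) > 1:
            raise UpdateError(
                f"merge component {component} mixes strands {sorted(strands)}"
            )
        members = sorted(
            component,
            key=lambda g: (reference.genes[g].seqid, reference.genes[g].start, g),
        )
        joiners = sorted(
            c.transcript_id
            for c in spanning
            if set(c.ref_gene_ids) <= set(component)
        )
        merge_actions.append((members, tuple(joiners)))
    merge_actions.sort(key=lambda m: _gene_sort_key(reference, m[0]))

    # intergenic transcripts: length filter, then overlap clustering
    novel_tx: List[TranscriptModel] = []
    for c in comparisons:
        if c.code != ClassCode.INTERGENIC:
            continue
        t = ev_tx[c.transcript_id]
        if not t.is_multi_exon and t.length < config.min_novel_single_exon_len:
            discarded.append(c.transcript_id)
        else:
            novel_tx.append(t)
    clusters = _cluster_by_overlap(novel_tx)
    clusters.sort(key=lambda txs: (txs[0].seqid, min(t.start for t in txs)))

    reserved = set(reference.genes)
    alloc = _GeneIdAllocator(config, reserved)
    for members, joiners in merge_actions:
        actions.append(
            UpdateAction(
                kind="MERGE",
                evidence_transcript_ids=joiners,
                target_gene_ids=tuple(members),
                new_gene_id=alloc.next(),
            )
        )
    for txs in clusters:
        actions.append(
            UpdateAction(
                kind="NEW_GENE",
                evidence_transcript_ids=tuple(
                    sorted(t.transcript_id for t in txs)
                ),
                target_gene_ids=(),
                new_gene_id=alloc.next(),
            )
        )

    return UpdatePlan(
        actions=actions,
        id_counter_start=config.id_start,
        discarded_transcript_ids=tuple(discarded),
    )


def _cluster_by_overlap(txs: List[TranscriptModel]) -> List[List[TranscriptModel]]:
    """Single-linkage clustering of transcripts by same-strand exon overlap."""
    uf = _UnionFind()
    trees: Dict[Tuple[str, str], IntervalTree] = {}
    for t in txs:
        uf.find(t.transcript_id)
        qstrands = ("+", "-", ".") if t.strand == "." else (t.strand, ".")
        for e in t.exons:
            for strand in qstrands:
                tree = trees.get((t.seqid, strand))
                if tree is None:
                    continue
                for iv in tree.overlap(e.start, e.end + 1):
                    uf.union(t.transcript_id, iv.data)
        tree = trees.setdefault((t.seqid, t.strand), IntervalTree())
        for e in t.exons:
            tree.addi(e.start, e.end + 1, t.transcript_id)
    by_id = {t.transcript_id: t for t in txs}
    clusters = []
    for comp in uf.components():
        members = sorted(
            (by_id[tid] for tid in comp),
            key=lambda t: (t.start, t.transcript_id),
        )
        clusters.append(members)
    return clusters


def _next_free_isoform_id(gene_id: str, taken: Set[str]) -> str:
    n = 1
    while f"{gene_id}.t{n}" in taken:
        n += 1
    return f"{gene_id}.t{n}"


def apply_updates(
    reference: AnnotationSet,
    evidence: AnnotationSet,
    plan: UpdatePlan,
) -> Tuple[AnnotationSet, UpdateReport]:
    """Apply a plan, returning the updated annotation and its accounting.

    Reference genes untouched by any action pass through unchanged,
    attributes byte-identical; every reference transcript identifier
    appears exactly once in the output.
    """
    ev_tx = {t.transcript_id: t for g in evidence.genes.values()
             for t in g.transcripts}
    out_genes: Dict[str, GeneModel] = dict(reference.genes)
    all_tx_ids: Set[str] = set(reference.transcript_to_gene())

    added_per_gene: Counter = Counter()
    merge_distribution: Counter = Counter()
    n_novel = 0

    for action in plan.actions:
        if action.kind == "ADD_ISOFORM":
            gid = action.target_gene_ids[0]
            gene = out_genes[gid]
            new_txs = list(gene.transcripts)
            for tid in action.evidence_transcript_ids:
                src = ev_tx[tid]
                new_id = _next_free_isoform_id(gid, all_tx_ids)
                all_tx_ids.add(new_id)
                new_txs.append(
                    TranscriptModel(
                        transcript_id=new_id,
                        gene_id=gid,
                        exons=src.exons,
                        attributes=dict(src.attributes),
                    )
                )
                added_per_gene[gid] += 1
            out_genes[gid] = GeneModel(
                gene_id=gid,
                transcripts=tuple(new_txs),
                attributes=gene.attributes,
            )
        elif action.kind == "MERGE":
            new_gid = action.new_gene_id
            if new_gid in out_genes:
                raise UpdateError(f"new gene id {new_gid!r} already exists")
            subunits = sorted(
                (out_genes[g] for g in action.target_gene_ids),
                key=lambda g: (g.start, g.gene_id),
            )
            merged_attrs: Dict[str, str] = {}
            for g in subunits:
                for k, v in g.attributes.items():
                    merged_attrs[k] = merged_attrs[k] + ";" + v \
                        if k in merged_attrs else v
            txs = [
                TranscriptModel(
                    transcript_id=t.transcript_id,
                    gene_id=new_gid,
                    exons=t.exons,
                    attributes=dict(t.attributes),
                )
                for g in subunits
                for t in g.transcripts
            ]
            for tid in action.evidence_transcript_ids:
                src = ev_tx[tid]
                new_id = _next_free_isoform_id(new_gid, all_tx_ids)
                all_tx_ids.add(new_id)
                txs.append(
                    TranscriptModel(
                        transcript_id=new_id,
                        gene_id=new_gid,
                        exons=src.exons,
                        attributes=dict(src.attributes),
                    )
                )
            for g in action.target_gene_ids:
                del out_genes[g]
            out_genes[new_gid] = GeneModel(
                gene_id=new_gid, transcripts=tuple(txs), attributes=merged_attrs
            )
            merge_distribution[len(action.target_gene_ids)] += 1
        elif action.kind == "NEW_GENE":
            new_gid = action.new_gene_id
            if new_gid in out_genes:
                raise UpdateError(f"new gene id {new_gid!r} already exists")
            members = sorted(
                (ev_tx[tid] for tid in action.evidence_transcript_ids),
                key=lambda t: (t.start, t.transcript_id),
            )
            txs = []
            for t in members:
                new_id = _next_free_isoform_id(new_gid, all_tx_ids)
                all_tx_ids.add(new_id)
                txs.append(
                    TranscriptModel(
                        transcript_id=new_id,
                        gene_id=new_gid,
                        exons=t.exons,
                        attributes=dict(t.attributes),
                    )
                )
            out_genes[new_gid] = GeneModel(
                gene_id=new_gid, transcripts=tuple(txs), attributes={}
            )
            n_novel += 1
        else:
            raise UpdateError(f"unknown action kind {action.kind!r}")

    report = UpdateReport(
        n_isoforms_added=sum(added_per_gene.values()),
        n_genes_gaining_isoforms=len(added_per_gene),
        max_isoforms_added_to_one_gene=(
            max(added_per_gene.values()) if added_per_gene else 0
        ),
        merge_distribution=dict(merge_distribution),
        n_novel_genes=n_novel,
        n_discarded=len(plan.discarded_transcript_ids),
    )
    updated = AnnotationSet(
        list(out_genes.values()), provenance="updated"
    )
    return updated, report


@dataclass(frozen=True)
class MergeDistributionTable:
    """Distribution of merge sizes: rows of (k genes joined, instances)."""

    rows: Tuple[Tuple[int, int], ...]
    total: int

    def to_tsv(self) -> str:
        lines = ["# of joined neighbors\t# of instances"]
        for k, count in self.rows:
            lines.append(f"{k}\t{count}")
        lines.append(f"total\t{self.total}")
        return "\n".join(lines) + "\n"


def merge_distribution_table(
    report: UpdateReport | Mapping[int, int],
) -> MergeDistributionTable:
    """Tabulate a merge distribution, ascending in k, with a grand total."""
    dist = (
        report.merge_distribution
        if isinstance(report, UpdateReport)
        else report
    )
    for k in dist:
        if k < 2:
            raise UpdateError(f"merge size {k} < 2 is not a merge")
    rows = tuple(sorted((int(k), int(v)) for k, v in dist.items()))
    return MergeDistributionTable(rows=rows, total=sum(v for _, v in rows))
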
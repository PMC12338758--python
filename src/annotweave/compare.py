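"""Classify assembled evidence transcripts against a reference annotation.

Each evidence transcript receives exactly one class code from a fixed
decision ladder (first match wins), where "touching" a gene means having
same-strand exonic overlap with it:

1. ``EXACT`` — identical intron chain to a reference transcript
   (multi-exon), or, for single-exon transcripts, reciprocal exonic
   overlap of at least ``single_exon_min_overlap`` (default 0.8) with a
   single-exon reference transcript.
2. ``SPANS_MULTIPLE`` — touches two or more reference genes; the
   signature of two annotated loci forming one transcription unit.
3. ``NOVEL_ISOFORM`` — multi-exon, shares at least one intron (both
   boundaries) with exactly one gene, but no identical chain.
4. ``CONTAINED`` — intron chain is a contiguous sub-chain of a reference
   transcript's chain, or a single-exon transcript lying inside one
   reference exon.
5. ``EXONIC_OVERLAP_ONLY`` — touches exactly one gene, no shared intron.
6. ``OPPOSITE_STRAND`` — exonic overlap only with genes on the other
   strand.
7. ``INTERGENIC`` — no exonic overlap with any reference gene.

Exact-match semantics deliberately ignore the outer coordinates of the
terminal exons: RNA-seq evidence rarely pins transcription start and end
sites, so identity is identity of introns.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Optional, Set, Tuple

from intervaltree import IntervalTree

from .models import (
    AnnotationSet,
    GenomicInterval,
    TranscriptModel,
    strands_compatible,
)

DEFAULT_SINGLE_EXON_MIN_OVERLAP = 0.8


class ClassCode(str, Enum):
    EXACT = "EXACT"
    NOVEL_ISOFORM = "NOVEL_ISOFORM"
    CONTAINED = "CONTAINED"
    SPANS_MULTIPLE = "SPANS_MULTIPLE"
    INTERGENIC = "INTERGENIC"
    OPPOSITE_STRAND = "OPPOSITE_STRAND"
    EXONIC_OVERLAP_ONLY = "EXONIC_OVERLAP_ONLY"


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of classifying one evidence transcript."""

    transcript_id: str
    code: ClassCode
    ref_gene_ids: Tuple[str, ...] = ()
    matched_ref_transcript_id: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.code == ClassCode.INTERGENIC) != (len(self.ref_gene_ids) == 0):
            raise ValueError(
                "INTERGENIC iff no reference genes touched "
                f"(code={self.code}, genes={self.ref_gene_ids})"
            )
        if self.code == ClassCode.SPANS_MULTIPLE and len(self.ref_gene_ids) < 2:
            raise ValueError("SPANS_MULTIPLE requires >= 2 reference genes")
        if self.code == ClassCode.EXACT and (
            self.matched_ref_transcript_id is None or len(self.ref_gene_ids) != 1
        ):
            raise ValueError("EXACT requires a matched transcript and one gene")


class ReferenceIndex:
    """Interval and intron-chain indexes over a reference annotation."""

    def __init__(self, reference: AnnotationSet) -> None:
        self.reference = reference
        # (seqid, strand) -> IntervalTree of exons; data = (gene_id, tx_id)
        self._exon_trees: Dict[Tuple[str, str], IntervalTree] = {}
        # (seqid, strand, intron chain) -> sorted [(tx_id, gene_id)]
        self._chains: Dict[Tuple[str, str, Tuple[Tuple[int, int], ...]],
                           List[Tuple[str, str]]] = {}
        # (seqid, strand, intron) -> set of gene_ids
        self._introns: Dict[Tuple[str, str, Tuple[int, int]], Set[str]] = {}
        self._tx: Dict[str, TranscriptModel] = {}
        self._tx_gene: Dict[str, str] = {}

        for gene in reference.genes.values():
            for t in gene.transcripts:
                self._tx[t.transcript_id] = t
                self._tx_gene[t.transcript_id] = gene.gene_id
                tree = self._exon_trees.setdefault(
                    (t.seqid, t.strand), IntervalTree()
                )
                for e in t.exons:
                    tree.addi(e.start, e.end + 1, (gene.gene_id, t.transcript_id))
                if t.is_multi_exon:
                    key = (t.seqid, t.strand, t.introns)
                    self._chains.setdefault(key, []).append(
                        (t.transcript_id, gene.gene_id)
                    )
                    for intron in t.introns:
                        self._introns.setdefault(
                            (t.seqid, t.strand, intron), set()
                        ).add(gene.gene_id)
        for entries in self._chains.values():
            entries.sort()

    def transcript(self, transcript_id: str) -> TranscriptModel:
        return self._tx[transcript_id]

    def gene_of(self, transcript_id: str) -> str:
        return self._tx_gene[transcript_id]

    def overlapping_exons(self, exon: GenomicInterval):
        """All reference exons overlapping ``exon`` on any strand.

        Yields (ref_strand, gene_id, transcript_id, ref_start, ref_end).
        """
        for strand in ("+", "-", "."):
            tree = self._exon_trees.get((exon.seqid, strand))
            if tree is None:
                continue
            for iv in tree.overlap(exon.start, exon.end + 1):
                gid, tid = iv.data
                yield strand, gid, tid, iv.begin, iv.end - 1

    def chain_matches(self, t: TranscriptModel) -> List[Tuple[str, str]]:
        return self._chains.get((t.seqid, t.strand, t.introns), [])

    def intron_genes(self, t: TranscriptModel, intron: Tuple[int, int]) -> Set[str]:
        return self._introns.get((t.seqid, t.strand, intron), set())

    def gene_transcripts(self, gene_id: str) -> Tuple[TranscriptModel, ...]:
        return self.reference.genes[gene_id].transcripts


def _is_contiguous_subchain(
    sub: Tuple[Tuple[int, int], ...], chain: Tuple[Tuple[int, int], ...]
) -> bool:
    if not sub or len(sub) > len(chain):
        return False
    for i in range(len(chain) - len(sub) + 1):
        if chain[i:i + len(sub)] == sub:
            return True
    return False


def classify_transcript(
    t: TranscriptModel,
    reference: AnnotationSet | ReferenceIndex,
    single_exon_min_overlap: float = DEFAULT_SINGLE_EXON_MIN_OVERLAP,
) -> ComparisonResult:
    """Assign a class code to one evidence transcript.

    ``reference`` may be an :class:`AnnotationSet` (indexed on the fly)
    or a pre-built :class:`ReferenceIndex` for batch use.
    """
    index = (
        reference
        if isinstance(reference, ReferenceIndex)
        else ReferenceIndex(reference)
    )

    same_genes: Set[str] = set()
    opp_genes: Set[str] = set()
    # single-exon reference transcripts overlapping t (for EXACT/CONTAINED)
    candidate_single: Dict[str, TranscriptModel] = {}
    containing_exon = False
    for exon in t.exons:
        for strand, gid, tid, rstart, rend in index.overlapping_exons(exon):
            if strands_compatible(t.strand, strand):
                same_genes.add(gid)
                ref_t = index.transcript(tid)
                if not ref_t.is_multi_exon:
                    candidate_single[tid] = ref_t
                if rstart <= exon.start and exon.end <= rend:
                    containing_exon = True
            else:
                opp_genes.add(gid)
    opp_genes -= same_genes

    # (1) EXACT
    if t.is_multi_exon:
        matches = index.chain_matches(t)
        if matches:
            tid, gid = matches[0]  # lexicographically smallest transcript_id
            return ComparisonResult(t.transcript_id, ClassCode.EXACT, (gid,), tid)
    else:
        best: Optional[Tuple[float, str, str]] = None
        exon = t.exons[0]
        for tid in sorted(candidate_single):
            ref_t = candidate_single[tid]
            ov = exon.overlap_len(ref_t.exons[0])
            reciprocal = min(ov / exon.length, ov / ref_t.length)
            if reciprocal >= single_exon_min_overlap:
                key = (-reciprocal, tid)
                if best is None or key < (-best[0], best[1]):
                    best = (reciprocal, tid, index.gene_of(tid))
        if best is not None:
            _, tid, gid = best
            return ComparisonResult(t.transcript_id, ClassCode.EXACT, (gid,), tid)

    # (2) SPANS_MULTIPLE
    if len(same_genes) >= 2:
        return ComparisonResult(
            t.transcript_id, ClassCode.SPANS_MULTIPLE, tuple(sorted(same_genes))
        )

    if len(same_genes) == 1:
        gene_id = next(iter(same_genes))
        genes_tuple = (gene_id,)

        # (3) NOVEL_ISOFORM
        if t.is_multi_exon and any(
            gene_id in index.intron_genes(t, intron) for intron in t.introns
        ):
            return ComparisonResult(
                t.transcript_id, ClassCode.NOVEL_ISOFORM, genes_tuple
            )

        # (4) CONTAINED
        if t.is_multi_exon:
            for ref_t in index.gene_transcripts(gene_id):
                if strands_compatible(t.strand, ref_t.strand) and \
                        _is_contiguous_subchain(t.introns, ref_t.introns):
                    return ComparisonResult(
                        t.transcript_id, ClassCode.CONTAINED, genes_tuple
                    )
        elif containing_exon:
            return ComparisonResult(
                t.transcript_id, ClassCode.CONTAINED, genes_tuple
            )

        # (5) EXONIC_OVERLAP_ONLY
        return ComparisonResult(
            t.transcript_id, ClassCode.EXONIC_OVERLAP_ONLY, genes_tuple
        )

    # (6) OPPOSITE_STRAND
    if opp_genes:
        return ComparisonResult(
            t.transcript_id, ClassCode.OPPOSITE_STRAND, tuple(sorted(opp_genes))
        )

    # (7) INTERGENIC
    return ComparisonResult(t.transcript_id, ClassCode.INTERGENIC)


def classify_all(
    evidence: AnnotationSet,
    reference: AnnotationSet,
    single_exon_min_overlap: float = DEFAULT_SINGLE_EXON_MIN_OVERLAP,
) -> List[ComparisonResult]:
    """Classify every evidence transcript, in (seqid, start, id) order."""
    index = ReferenceIndex(reference)
    return [
        classify_transcript(t, index, single_exon_min_overlap)
        for t in evidence.transcripts()
    ]


def comparison_table(results: List[ComparisonResult]) -> str:
    """Comparison results as a TSV block."""
    lines = ["transcript_id\tclass_code\tref_gene_ids\tmatched_ref_transcript_id"]
    for r in results:
        lines.append(
            "\t".join(
                (
                    r.transcript_id,
                    r.code.value,
                    ",".join(r.ref_gene_ids),
                    r.matched_ref_transcript_id or "",
                )
            )
        )
    return "\n".join(lines) + "\n"
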
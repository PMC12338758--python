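"""Exhaustive pairwise transcript classification.

A deliberately simple reference implementation of the class-code ladder:
every evidence transcript is compared against every reference transcript
with no interval index and no shared machinery beyond the data model.
Quadratic in the number of transcripts, so only suitable for small
inputs; it exists as an independent cross-check of
:mod:`annotweave.compare`.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

from .compare import ClassCode, ComparisonResult, DEFAULT_SINGLE_EXON_MIN_OVERLAP
from .models import AnnotationSet, TranscriptModel, strands_compatible


def _pair_overlap(a: TranscriptModel, b: TranscriptModel) -> int:
    if a.seqid != b.seqid:
        return 0
    total = 0
    for ea in a.exons:
        for eb in b.exons:
            total += max(0, min(ea.end, eb.end) - max(ea.start, eb.start) + 1)
    return total


def classify_transcript_naive(
    t: TranscriptModel,
    reference: AnnotationSet,
    single_exon_min_overlap: float = DEFAULT_SINGLE_EXON_MIN_OVERLAP,
) -> ComparisonResult:
    same_genes = set()
    opp_genes = set()
    exact_multi: List[Tuple[str, str]] = []
    exact_single: List[Tuple[float, str, str]] = []
    shared_intron_genes = set()
    subchain_genes = set()
    contained_single = False

    for gene in reference.genes.values():
        for r in gene.transcripts:
            ov = _pair_overlap(t, r)
            if ov == 0:
                continue
            if strands_compatible(t.strand, r.strand):
                same_genes.add(gene.gene_id)
            else:
                opp_genes.add(gene.gene_id)
                continue
            if t.is_multi_exon and r.is_multi_exon and t.introns == r.introns:
                exact_multi.append((r.transcript_id, gene.gene_id))
            if not t.is_multi_exon and not r.is_multi_exon:
                reciprocal = min(ov / t.length, ov / r.length)
                if reciprocal >= single_exon_min_overlap:
                    exact_single.append((reciprocal, r.transcript_id, gene.gene_id))
            if t.is_multi_exon and r.is_multi_exon:
                if set(t.introns) & set(r.introns):
                    shared_intron_genes.add(gene.gene_id)
                n = len(t.introns)
                for i in range(len(r.introns) - n + 1):
                    if r.introns[i:i + n] == t.introns:
                        subchain_genes.add(gene.gene_id)
                        break
            if not t.is_multi_exon:
                e = t.exons[0]
                for re_ in r.exons:
                    if re_.start <= e.start and e.end <= re_.end:
                        contained_single = True
    opp_genes -= same_genes

    if t.is_multi_exon and exact_multi:
        tid, gid = min(exact_multi)
        return ComparisonResult(t.transcript_id, ClassCode.EXACT, (gid,), tid)
    if not t.is_multi_exon and exact_single:
        best = min(exact_single, key=lambda c: (-c[0], c[1]))
        return ComparisonResult(
            t.transcript_id, ClassCode.EXACT, (best[2],), best[1]
        )
    if len(same_genes) >= 2:
        return ComparisonResult(
            t.transcript_id, ClassCode.SPANS_MULTIPLE, tuple(sorted(same_genes))
        )
    if len(same_genes) == 1:
        gid = next(iter(same_genes))
        if t.is_multi_exon and gid in shared_intron_genes:
            return ComparisonResult(t.transcript_id, ClassCode.NOVEL_ISOFORM, (gid,))
        if t.is_multi_exon and gid in subchain_genes:
            return ComparisonResult(t.transcript_id, ClassCode.CONTAINED, (gid,))
        if not t.is_multi_exon and contained_single:
            return ComparisonResult(t.transcript_id, ClassCode.CONTAINED, (gid,))
        return ComparisonResult(
            t.transcript_id, ClassCode.EXONIC_OVERLAP_ONLY, (gid,)
        )
    if opp_genes:
        return ComparisonResult(
            t.transcript_id, ClassCode.OPPOSITE_STRAND, tuple(sorted(opp_genes))
        )
    return ComparisonResult(t.transcript_id, ClassCode.INTERGENIC)


def classify_all_naive(
    evidence: AnnotationSet,
    reference: AnnotationSet,
    single_exon_min_overlap: float = DEFAULT_SINGLE_EXON_MIN_OVERLAP,
) -> List[ComparisonResult]:
    return [
        classify_transcript_naive(t, reference, single_exon_min_overlap)
        for t in evidence.transcripts()
    ]
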
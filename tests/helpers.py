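"""Shared construction helpers for the test suite."""

from __future__ import annotations

from typing import Iterable, Sequence, Tuple

from annotweave.models import (
    AnnotationSet,
    GenomicInterval,
    GeneModel,
    TranscriptModel,
)


def tx(
    tid: str,
    gid: str,
    exons: Sequence[Tuple[int, int]],
    strand: str = "+",
    seqid: str = "Scaffold1",
    attributes: dict | None = None,
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        exons=tuple(
            GenomicInterval(seqid, s, e, strand) for s, e in exons
        ),
        attributes=attributes or {},
    )


def annotation(transcripts: Iterable[TranscriptModel],
               provenance: str = "reference") -> AnnotationSet:
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    genes = [
        GeneModel(gene_id=g, transcripts=tuple(ts))
        for g, ts in by_gene.items()
    ]
    return AnnotationSet(genes, provenance=provenance)
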
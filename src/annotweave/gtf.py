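"""GTF reading, writing and whole-annotation summary statistics.

The dialect is GTF2.2: nine tab-separated columns, attributes written as
``key "value";`` pairs.  Exon features are authoritative — gene and
transcript header lines are optional metadata (StringTie output, for
instance, has no gene lines) and, when present, must agree with the
extents derived from the exons.  Output is fully deterministic: the same
annotation always serialises to byte-identical text, and
``parse_gtf(write_gtf(a)) == a`` for every valid set.
"""

from __future__ import annotations

import re
from typing import Dict, Iterable, List, Optional, TextIO, Tuple

from ._util import round_half_up, round_ratio
from .models import (
    AnnotationSet,
    AssemblyStats,
    GenomicInterval,
    GeneModel,
    GtfParseError,
    GtfValidationError,
    TranscriptModel,
)

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"\s*;')

# attribute keys that are structural, not free annotation text
_RESERVED_KEYS = {"gene_id", "transcript_id", "exon_number"}


def _parse_attributes(text: str, line_no: int) -> Dict[str, str]:
    attrs: Dict[str, str] = {}
    for key, value in _ATTR_RE.findall(text):
        if key not in attrs:  # first occurrence wins
            attrs[key] = value
    if not attrs and text.strip():
        raise GtfParseError(f"line {line_no}: unparseable attribute column {text!r}")
    return attrs


def _as_lines(source) -> List[str]:
    if isinstance(source, str):
        if not source or "\n" in source or "\t" in source:
            return source.splitlines()
        with open(source, "r", encoding="utf-8") as fh:
            return fh.read().splitlines()
    return [line for line in source]


def parse_gtf(source, provenance: str = "reference") -> AnnotationSet:
    """Parse GTF text into an :class:`AnnotationSet`.

    ``source`` may be a path, a block of GTF text, an open file, or any
    iterable of lines.  Comment lines (``#``) are skipped; feature types
    other than gene/transcript/exon are ignored.
    """
    exon_rows: List[Tuple[str, int, int, str, str, str, Dict[str, str], int]] = []
    tx_headers: Dict[str, Tuple[str, int, int, str, str, Dict[str, str]]] = {}
    gene_headers: Dict[str, Dict[str, str]] = {}

    for line_no, raw in enumerate(_as_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GtfParseError(
                f"line {line_no}: expected 9 tab-separated columns, "
                f"got {len(cols)}"
            )
        seqid, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = cols
        try:
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise GtfParseError(
                f"line {line_no}: non-integer coordinates "
                f"{start_s!r}/{end_s!r}"
            ) from None
        attrs = _parse_attributes(attr_s, line_no)
        if feature == "exon":
            if "gene_id" not in attrs or "transcript_id" not in attrs:
                raise GtfParseError(
                    f"line {line_no}: exon lacks gene_id/transcript_id"
                )
            if end < start:
                raise GtfValidationError(
                    f"line {line_no}: exon end {end} < start {start}"
                )
            exon_rows.append(
                (seqid, start, end, strand, attrs["gene_id"],
                 attrs["transcript_id"], attrs, line_no)
            )
        elif feature == "transcript":
            tid = attrs.get("transcript_id")
            if tid is None:
                raise GtfParseError(
                    f"line {line_no}: transcript line lacks transcript_id"
                )
            tx_headers[tid] = (
                seqid, start, end, strand, attrs.get("gene_id", ""), attrs
            )
        elif feature == "gene":
            gid = attrs.get("gene_id")
            if gid is None:
                raise GtfParseError(f"line {line_no}: gene line lacks gene_id")
            gene_headers[gid] = attrs

    # group exons by transcript, preserving a deterministic order
    by_tx: Dict[str, List[Tuple[str, int, int, str, Dict[str, str], int]]] = {}
    tx_gene: Dict[str, str] = {}
    for seqid, start, end, strand, gid, tid, attrs, line_no in exon_rows:
        if tid in tx_gene and tx_gene[tid] != gid:
            raise GtfValidationError(
                f"line {line_no}: transcript_id {tid!r} appears under gene_ids "
                f"{tx_gene[tid]!r} and {gid!r}"
            )
        tx_gene[tid] = gid
        by_tx.setdefault(tid, []).append((seqid, start, end, strand, attrs, line_no))

    transcripts: Dict[str, TranscriptModel] = {}
    for tid, rows in by_tx.items():
        rows.sort(key=lambda r: (r[1], r[2]))
        exons = tuple(
            GenomicInterval(seqid=r[0], start=r[1], end=r[2], strand=r[3])
            for r in rows
        )
        # free attributes: transcript header if present, else first exon line
        if tid in tx_headers:
            hseq, hstart, hend, hstrand, hgid, hattrs = tx_headers[tid]
            if hseq != exons[0].seqid:
                raise GtfValidationError(
                    f"transcript {tid!r}: header seqid {hseq!r} disagrees with "
                    f"exon seqid {exons[0].seqid!r}"
                )
            if hgid and hgid != tx_gene[tid]:
                raise GtfValidationError(
                    f"transcript {tid!r}: header gene_id {hgid!r} disagrees "
                    f"with exon gene_id {tx_gene[tid]!r}"
                )
            if (hstart, hend) != (exons[0].start, exons[-1].end):
                raise GtfValidationError(
                    f"transcript {tid!r}: header extent {hstart}-{hend} "
                    f"disagrees with exon extent "
                    f"{exons[0].start}-{exons[-1].end}"
                )
            free = {k: v for k, v in hattrs.items() if k not in _RESERVED_KEYS}
        else:
            free = {k: v for k, v in rows[0][4].items() if k not in _RESERVED_KEYS}
        transcripts[tid] = TranscriptModel(
            transcript_id=tid, gene_id=tx_gene[tid], exons=exons, attributes=free
        )

    for tid, (hseq, hstart, hend, hstrand, hgid, hattrs) in tx_headers.items():
        if tid not in transcripts:
            raise GtfValidationError(
                f"transcript {tid!r} declared but has no exon features"
            )

    by_gene: Dict[str, List[TranscriptModel]] = {}
    for t in transcripts.values():
        by_gene.setdefault(t.gene_id, []).append(t)

    genes = []
    for gid in sorted(by_gene):
        gattrs = {
            k: v
            for k, v in gene_headers.get(gid, {}).items()
            if k not in _RESERVED_KEYS
        }
        genes.append(
            GeneModel(gene_id=gid, transcripts=tuple(by_gene[gid]), attributes=gattrs)
        )
    return AnnotationSet(genes, provenance=provenance)


def _fmt_attrs(pairs: Iterable[Tuple[str, str]]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs)


def write_gtf(annotation: AnnotationSet, stream: Optional[TextIO] = None) -> str:
    """Serialise an annotation as GTF text.

    Emits gene, transcript and exon features ordered by (seqid, start,
    gene_id); exons within a transcript ascending by start with
    ``exon_number`` attributes.  When ``stream`` is given the text is also
    written there.  Same input gives byte-identical output.
    """
    out: List[str] = []
    source = "annotweave"
    for gene in annotation.genes_sorted():
        gpairs = [("gene_id", gene.gene_id)] + list(gene.attributes.items())
        out.append(
            "\t".join(
                (gene.seqid, source, "gene", str(gene.start), str(gene.end),
                 ".", gene.strand, ".", _fmt_attrs(gpairs))
            )
        )
        for t in gene.transcripts:
            tpairs = [
                ("gene_id", gene.gene_id),
                ("transcript_id", t.transcript_id),
            ] + list(t.attributes.items())
            out.append(
                "\t".join(
                    (t.seqid, source, "transcript", str(t.start), str(t.end),
                     ".", t.strand, ".", _fmt_attrs(tpairs))
                )
            )
            for i, e in enumerate(t.exons, start=1):
                epairs = [
                    ("gene_id", gene.gene_id),
                    ("transcript_id", t.transcript_id),
                    ("exon_number", str(i)),
                ]
                out.append(
                    "\t".join(
                        (e.seqid, source, "exon", str(e.start), str(e.end),
                         ".", e.strand, ".", _fmt_attrs(epairs))
                    )
                )
    text = "\n".join(out) + ("\n" if out else "")
    if stream is not None:
        stream.write(text)
    return text


def summarize(annotation: AnnotationSet) -> AssemblyStats:
    """Compute whole-annotation summary statistics.

    Transcript length is exonic length (summed exon lengths).  The mean
    transcripts-per-gene ratio is reported to one decimal; length means
    and medians to the nearest nucleotide (half-up).
    """
    if annotation.n_genes == 0:
        raise GtfValidationError("cannot summarize an empty annotation")
    lengths = sorted(t.length for g in annotation.genes.values()
                     for t in g.transcripts)
    n_tx = len(lengths)
    n_genes = annotation.n_genes
    per_gene = [len(g.transcripts) for g in annotation.genes.values()]
    mid = n_tx // 2
    if n_tx % 2:
        median = float(lengths[mid])
    else:
        median = (lengths[mid - 1] + lengths[mid]) / 2
    return AssemblyStats(
        n_genes=n_genes,
        n_transcripts=n_tx,
        mean_tx_per_gene=round_ratio(n_tx, n_genes, 1),
        max_tx_per_gene=max(per_gene),
        mean_tx_length=int(round_ratio(sum(lengths), n_tx, 0)),
        median_tx_length=int(round_half_up(median, 0)),
        max_tx_length=lengths[-1],
    )
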
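"""Core annotation containers.

The unit of everything downstream is the :class:`TranscriptModel` — an
ordered chain of exons on one strand of one sequence.  Transcripts are
grouped into :class:`GeneModel` loci and whole annotations are held in an
:class:`AnnotationSet`.  All coordinates follow the GTF convention:
1-based, inclusive at both ends.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Optional, Tuple

from ._util import round_half_up

VALID_STRANDS = ("+", "-", ".")


class GtfError(ValueError):
    """Base class for annotation I/O and validation failures."""


class GtfParseError(GtfError):
    """A line could not be parsed as GTF."""


class GtfValidationError(GtfError):
    """Parsed features violate a structural invariant."""


def strands_compatible(a: str, b: str) -> bool:
    """True when two strand symbols can belong to the same transcription unit.

    ``.`` (unknown, permitted on single-exon transcripts only) is
    compatible with either explicit strand.
    """
    return a == "." or b == "." or a == b


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval [start, end] on one strand of a sequence."""

    seqid: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise GtfValidationError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise GtfValidationError(
                f"end ({self.end}) < start ({self.start}) on {self.seqid}"
            )
        if self.strand not in VALID_STRANDS:
            raise GtfValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_len(self, other: "GenomicInterval") -> int:
        """Number of shared bases; 0 when on different sequences."""
        if self.seqid != other.seqid:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.seqid == other.seqid
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """An exon chain with identifiers.

    Exons must be sorted ascending by start, pairwise disjoint, and share
    one seqid and strand.  Multi-exon transcripts must have an explicit
    strand because their intron chain is strand-dependent.
    """

    transcript_id: str
    gene_id: str
    exons: Tuple[GenomicInterval, ...]
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        exons = tuple(self.exons)
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "attributes", dict(self.attributes))
        if not exons:
            raise GtfValidationError(
                f"transcript {self.transcript_id!r} has no exons"
            )
        seqids = {e.seqid for e in exons}
        if len(seqids) > 1:
            raise GtfValidationError(
                f"transcript {self.transcript_id!r} spans sequences {sorted(seqids)}"
            )
        strands = {e.strand for e in exons}
        if len(strands) > 1:
            raise GtfValidationError(
                f"transcript {self.transcript_id!r} mixes strands {sorted(strands)}"
            )
        if len(exons) > 1 and exons[0].strand == ".":
            raise GtfValidationError(
                f"multi-exon transcript {self.transcript_id!r} requires an "
                "explicit strand"
            )
        for prev, cur in zip(exons, exons[1:]):
            if cur.start <= prev.end:
                raise GtfValidationError(
                    f"exons of {self.transcript_id!r} are unsorted or overlap "
                    f"({prev.start}-{prev.end} then {cur.start}-{cur.end})"
                )

    @property
    def seqid(self) -> str:
        return self.exons[0].seqid

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        """Exonic length: the sum of exon lengths."""
        return sum(e.length for e in self.exons)

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    @property
    def introns(self) -> Tuple[Tuple[int, int], ...]:
        """The intron chain: ordered (start, end) gaps between exons."""
        return tuple(
            (a.end + 1, b.start - 1) for a, b in zip(self.exons, self.exons[1:])
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: one or more transcripts sharing seqid and strand."""

    gene_id: str
    transcripts: Tuple[TranscriptModel, ...]
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        txs = tuple(
            sorted(self.transcripts, key=lambda t: (t.start, t.transcript_id))
        )
        object.__setattr__(self, "transcripts", txs)
        object.__setattr__(self, "attributes", dict(self.attributes))
        if not txs:
            raise GtfValidationError(f"gene {self.gene_id!r} has no transcripts")
        if {t.seqid for t in txs} != {txs[0].seqid}:
            raise GtfValidationError(
                f"gene {self.gene_id!r} has transcripts on multiple sequences"
            )
        explicit = {t.strand for t in txs if t.strand != "."}
        if len(explicit) > 1:
            raise GtfValidationError(
                f"gene {self.gene_id!r} has transcripts on both strands"
            )
        for t in txs:
            if t.gene_id != self.gene_id:
                raise GtfValidationError(
                    f"transcript {t.transcript_id!r} carries gene_id "
                    f"{t.gene_id!r} inside gene {self.gene_id!r}"
                )

    @property
    def seqid(self) -> str:
        return self.transcripts[0].seqid

    @property
    def strand(self) -> str:
        explicit = {t.strand for t in self.transcripts if t.strand != "."}
        return explicit.pop() if explicit else "."

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)


class AnnotationSet:
    """A collection of gene models keyed by gene_id.

    ``provenance`` labels where the annotation came from (``reference``,
    ``evidence`` or ``updated``); it is carried as metadata and ignored in
    equality comparisons.
    """

    def __init__(self, genes: Mapping[str, GeneModel] | list[GeneModel] = (),
                 provenance: str = "reference") -> None:
        if isinstance(genes, Mapping):
            gene_list = list(genes.values())
        else:
            gene_list = list(genes)
        self.genes: Dict[str, GeneModel] = {}
        seen_tx: Dict[str, str] = {}
        for g in gene_list:
            if g.gene_id in self.genes:
                raise GtfValidationError(f"duplicate gene_id {g.gene_id!r}")
            for t in g.transcripts:
                if t.transcript_id in seen_tx:
                    raise GtfValidationError(
                        f"transcript_id {t.transcript_id!r} appears under genes "
                        f"{seen_tx[t.transcript_id]!r} and {g.gene_id!r}"
                    )
                seen_tx[t.transcript_id] = g.gene_id
            self.genes[g.gene_id] = g
        self.provenance = provenance

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())

    def genes_sorted(self) -> list[GeneModel]:
        return sorted(
            self.genes.values(), key=lambda g: (g.seqid, g.start, g.gene_id)
        )

    def transcripts(self) -> Iterator[TranscriptModel]:
        """All transcripts in (seqid, start, transcript_id) order."""
        txs = [t for g in self.genes.values() for t in g.transcripts]
        txs.sort(key=lambda t: (t.seqid, t.start, t.transcript_id))
        return iter(txs)

    def transcript_to_gene(self) -> Dict[str, str]:
        return {
            t.transcript_id: g.gene_id
            for g in self.genes.values()
            for t in g.transcripts
        }

    def get_transcript(self, transcript_id: str) -> Optional[TranscriptModel]:
        for g in self.genes.values():
            for t in g.transcripts:
                if t.transcript_id == transcript_id:
                    return t
        return None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self.genes == other.genes

    def __repr__(self) -> str:
        return (
            f"AnnotationSet(n_genes={self.n_genes}, "
            f"n_transcripts={self.n_transcripts}, provenance={self.provenance!r})"
        )


@dataclass(frozen=True)
class AssemblyStats:
    """Whole-annotation summary: counts and transcript length statistics.

    ``mean_tx_per_gene`` is reported to one decimal and the length means
    to the nearest nucleotide (half-up in both cases); lengths are exonic
    (summed exon lengths), not genomic span.
    """

    n_genes: int
    n_transcripts: int
    mean_tx_per_gene: float
    max_tx_per_gene: int
    mean_tx_length: int
    median_tx_length: int
    max_tx_length: int

    def to_tsv(self) -> str:
        rows = [
            ("N(Genes)", self.n_genes),
            ("N(Transcripts)", self.n_transcripts),
            ("Average transcripts per gene", self.mean_tx_per_gene),
            ("Max transcripts per gene", self.max_tx_per_gene),
            ("Average transcript length", self.mean_tx_length),
            ("Median transcript length", self.median_tx_length),
            ("Max transcript length", self.max_tx_length),
        ]
        return "".join(f"{k}\t{v}\n" for k, v in rows)
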
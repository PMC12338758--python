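"""Gene-level reconciliation of transcript-mode BUSCO results.

BUSCO run in transcriptome mode scores every transcript, so two isoforms
of one gene hitting the same ortholog are reported as "Duplicated" even
though the locus is single-copy.  Reconciliation maps each hit's
transcript back to its gene and recounts: an ortholog hit in exactly one
gene is complete-single, in two or more genes complete-duplicated;
otherwise a fragmented hit makes it fragmented, else missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional

from ._util import round_ratio

VALID_STATUSES = ("Complete", "Duplicated", "Fragmented", "Missing")


class BuscoError(ValueError):
    pass


@dataclass(frozen=True)
class BuscoRecord:
    busco_id: str
    status: str
    sequence_id: Optional[str] = None
    score: Optional[float] = None
    length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.status not in VALID_STATUSES:
            raise BuscoError(f"unknown BUSCO status {self.status!r}")
        if (self.status == "Missing") != (self.sequence_id is None):
            raise BuscoError(
                f"{self.busco_id}: Missing records have no sequence and "
                "vice versa"
            )


@dataclass(frozen=True)
class GeneLevelBuscoSummary:
    """Counts and percentages over the BUSCO set, after gene collapse."""

    n_total: int
    n_complete_single: int
    n_complete_duplicated: int
    n_fragmented: int
    n_missing: int

    def __post_init__(self) -> None:
        parts = (
            self.n_complete_single + self.n_complete_duplicated
            + self.n_fragmented + self.n_missing
        )
        if parts != self.n_total:
            raise BuscoError(
                f"categories sum to {parts}, expected n_total={self.n_total}"
            )

    @property
    def n_complete_total(self) -> int:
        return self.n_complete_single + self.n_complete_duplicated

    def percentages(self) -> Dict[str, float]:
        return {
            "complete_total": busco_percent(self.n_complete_total, self.n_total),
            "complete_single": busco_percent(self.n_complete_single, self.n_total),
            "complete_duplicated": busco_percent(
                self.n_complete_duplicated, self.n_total
            ),
            "fragmented": busco_percent(self.n_fragmented, self.n_total),
            "missing": busco_percent(self.n_missing, self.n_total),
        }

    def to_tsv(self) -> str:
        pct = self.percentages()
        rows = [
            ("complete-total", self.n_complete_total, pct["complete_total"]),
            ("complete-single", self.n_complete_single, pct["complete_single"]),
            ("complete-duplicated", self.n_complete_duplicated,
             pct["complete_duplicated"]),
            ("fragmented", self.n_fragmented, pct["fragmented"]),
            ("missing", self.n_missing, pct["missing"]),
        ]
        lines = ["category\tcount\t%"]
        lines += [f"{name}\t{count}\t{p:.2f}" for name, count, p in rows]
        lines.append(f"total\t{self.n_total}\t")
        return "\n".join(lines) + "\n"


def busco_percent(count: int, n_total: int) -> float:
    """Percentage of the BUSCO set, half-up to two decimals."""
    if n_total <= 0:
        raise BuscoError("n_total must be positive")
    if not 0 <= count <= n_total:
        raise BuscoError(f"count {count} outside [0, {n_total}]")
    return round_ratio(100 * count, n_total, 2)


def parse_busco_table(source) -> List[BuscoRecord]:
    """Parse a BUSCO ``full_table.tsv`` (transcript mode).

    Columns: Busco id, Status, Sequence, Score, Length.  Comment lines
    start with ``#``; an ortholog may occupy several rows (Duplicated).
    """
    if isinstance(source, str):
        if "\n" in source or "\t" in source:
            lines: Iterable[str] = source.splitlines()
        else:
            with open(source, "r", encoding="utf-8") as fh:
                lines = fh.read().splitlines()
    else:
        lines = [ln for ln in source]
    records = []
    for line in lines:
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.split("\t")
        busco_id, status = cols[0], cols[1] if len(cols) > 1 else ""
        sequence = cols[2] if len(cols) > 2 and cols[2] else None
        score = float(cols[3]) if len(cols) > 3 and cols[3] else None
        length = int(float(cols[4])) if len(cols) > 4 and cols[4] else None
        records.append(
            BuscoRecord(
                busco_id=busco_id,
                status=status,
                sequence_id=sequence,
                score=score,
                length=length,
            )
        )
    return records


def reconcile_gene_level(
    records: List[BuscoRecord],
    tx_to_gene: Mapping[str, str],
) -> GeneLevelBuscoSummary:
    """Collapse transcript-level hits to gene-level completeness.

    Complete outranks Fragmented: an ortholog with any Complete or
    Duplicated hit is complete (single when all its hits fall in one
    gene), regardless of additional fragmented hits.
    """
    complete_genes: Dict[str, set] = {}
    fragmented: set = set()
    all_ids: set = set()
    for r in records:
        all_ids.add(r.busco_id)
        if r.status == "Missing":
            continue
        if r.sequence_id not in tx_to_gene:
            raise BuscoError(
                f"BUSCO hit sequence {r.sequence_id!r} (ortholog "
                f"{r.busco_id}) is not a known transcript"
            )
        gene = tx_to_gene[r.sequence_id]
        if r.status in ("Complete", "Duplicated"):
            complete_genes.setdefault(r.busco_id, set()).add(gene)
        elif r.status == "Fragmented":
            fragmented.add(r.busco_id)

    n_single = n_dup = n_frag = n_miss = 0
    for bid in all_ids:
        genes = complete_genes.get(bid, set())
        if len(genes) == 1:
            n_single += 1
        elif len(genes) >= 2:
            n_dup += 1
        elif bid in fragmented:
            n_frag += 1
        else:
            n_miss += 1
    return GeneLevelBuscoSummary(
        n_total=len(all_ids),
        n_complete_single=n_single,
        n_complete_duplicated=n_dup,
        n_fragmented=n_frag,
        n_missing=n_miss,
    )
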
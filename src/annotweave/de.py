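"""Threshold-based summaries of differential-expression result tables.

The input is a DESeq2-style export (gene_id, baseMean, log2FoldChange,
pvalue, padj).  Significance uses strict inequalities: adjusted p-value
below ``padj_max`` (default 0.1) and |log2 fold change| above
``lfc_min`` (default 0.6).  "Four-fold or greater" regulation means
|log2FC| >= 2.  All operations are pure functions of the record list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from ._util import percent_label, percent_value

DEFAULT_PADJ_MAX = 0.1
DEFAULT_LFC_MIN = 0.6
DEFAULT_FOLD4_LFC = 2.0
P_FLOOR = 1e-10


class DEError(ValueError):
    pass


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    base_mean: float
    log2fc: float
    pvalue: Optional[float] = None
    padj: Optional[float] = None

    def __post_init__(self) -> None:
        if self.base_mean < 0:
            raise DEError(f"{self.gene_id}: baseMean must be >= 0")
        for name, p in (("pvalue", self.pvalue), ("padj", self.padj)):
            if p is not None and not 0 <= p <= 1:
                raise DEError(f"{self.gene_id}: {name}={p} outside [0, 1]")


def load_de_table(source) -> List[DERecord]:
    """Read a DESeq2 export (TSV or CSV, header required) into records.

    Recognised columns: gene_id (or the first column), baseMean,
    log2FoldChange, pvalue, padj.  ``NA`` p-values become absent.
    """
    import io

    if isinstance(source, str) and ("\n" in source or "\t" in source):
        source = io.StringIO(source)
    df = pd.read_csv(source, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene_id", df.columns[0])

    def col(name: str) -> str:
        if name.lower() not in cols:
            raise DEError(f"missing column {name!r} in DE table")
        return cols[name.lower()]

    records = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        pval = d[col("pvalue")]
        padj = d[col("padj")]
        records.append(
            DERecord(
                gene_id=str(d[gene_col]),
                base_mean=float(d[col("baseMean")]),
                log2fc=float(d[col("log2FoldChange")]),
                pvalue=None if pd.isna(pval) else float(pval),
                padj=None if pd.isna(padj) else float(padj),
            )
        )
    return records


def filter_significant(
    records: Sequence[DERecord],
    padj_max: float = DEFAULT_PADJ_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    """Significantly up- and down-regulated gene sets (strict thresholds).

    Records with absent padj are excluded, matching DESeq2's convention
    of NA adjusted p-values for independently filtered genes.
    """
    up, down = set(), set()
    for r in records:
        if r.padj is None or not r.padj < padj_max:
            continue
        if r.log2fc > lfc_min:
            up.add(r.gene_id)
        elif r.log2fc < -lfc_min:
            down.add(r.gene_id)
    return frozenset(up), frozenset(down)


@dataclass(frozen=True)
class TimepointSummary:
    """Significant sets and >= 4-fold bins for one timepoint."""

    day: str
    up: FrozenSet[str]
    down: FrozenSet[str]
    up_ge4fold: int
    down_ge4fold: int

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise DEError("a gene cannot be both up- and down-regulated")
        if self.up_ge4fold > len(self.up) or self.down_ge4fold > len(self.down):
            raise DEError(">= 4-fold bin exceeds its significant set")

    @property
    def up_ge4fold_percent(self) -> str:
        return percent_label(self.up_ge4fold, len(self.up)) if self.up else "0%"

    @property
    def down_ge4fold_percent(self) -> str:
        return percent_label(self.down_ge4fold, len(self.down)) if self.down else "0%"


def fold_bin_summary(
    up: FrozenSet[str],
    down: FrozenSet[str],
    records: Sequence[DERecord],
    day: str = "",
    fold4_lfc: float = DEFAULT_FOLD4_LFC,
) -> TimepointSummary:
    """Count how many significant genes changed four-fold or more.

    Four-fold or greater is |log2FC| >= ``fold4_lfc`` (inclusive).
    """
    lfc = {r.gene_id: r.log2fc for r in records}
    up_ge4 = sum(1 for g in up if lfc[g] >= fold4_lfc)
    down_ge4 = sum(1 for g in down if lfc[g] <= -fold4_lfc)
    return TimepointSummary(
        day=day, up=frozenset(up), down=frozenset(down),
        up_ge4fold=up_ge4, down_ge4fold=down_ge4,
    )


_REGIONS = ("d1_only", "d3_only", "d7_only", "d1_d3", "d1_d7", "d3_d7",
            "d1_d3_d7")


def venn3_partition(
    a: FrozenSet[str], b: FrozenSet[str], c: FrozenSet[str]
) -> Dict[str, int]:
    """Counts of the seven disjoint regions of a three-set Venn diagram."""
    return {
        "d1_only": len(a - b - c),
        "d3_only": len(b - a - c),
        "d7_only": len(c - a - b),
        "d1_d3": len((a & b) - c),
        "d1_d7": len((a & c) - b),
        "d3_d7": len((b & c) - a),
        "d1_d3_d7": len(a & b & c),
    }


@dataclass(frozen=True)
class OverlapTable:
    """Three-timepoint Venn partition for up and for down gene sets."""

    up_regions: Mapping[str, int]
    down_regions: Mapping[str, int]

    def __post_init__(self) -> None:
        for regions in (self.up_regions, self.down_regions):
            if set(regions) != set(_REGIONS):
                raise DEError(f"expected regions {_REGIONS}")


def overlap_sets(
    summary_d1: TimepointSummary,
    summary_d3: TimepointSummary,
    summary_d7: TimepointSummary,
) -> OverlapTable:
    return OverlapTable(
        up_regions=venn3_partition(
            summary_d1.up, summary_d3.up, summary_d7.up
        ),
        down_regions=venn3_partition(
            summary_d1.down, summary_d3.down, summary_d7.down
        ),
    )


@dataclass(frozen=True)
class TopTableEntry:
    gene_id: str
    base_mean: float
    log2fc: float
    padj: Optional[float]
    description: Optional[str] = None


def top_table(
    records: Sequence[DERecord],
    base_mean_min: float = 70.0,
    n: int = 10,
    padj_max: float = DEFAULT_PADJ_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
    annotations: Optional[Mapping[str, Tuple[str, float]]] = None,
    nss_evalue: float = 1e-10,
) -> Tuple[List[TopTableEntry], List[TopTableEntry]]:
    """Top-n up- and down-regulated genes by fold change.

    Only significant genes with baseMean >= ``base_mean_min`` compete.
    Ties in log2FC break lexicographically by gene id.  When an
    ``annotations`` map (gene -> (BLAST description, E-value)) is given,
    entries whose E-value exceeds ``nss_evalue`` are labelled "NSS"
    (no significant similarity).
    """
    up, down = filter_significant(records, padj_max, lfc_min)
    eligible = [
        r for r in records
        if r.base_mean >= base_mean_min and (r.gene_id in up or r.gene_id in down)
    ]

    def entry(r: DERecord) -> TopTableEntry:
        desc = None
        if annotations is not None:
            hit = annotations.get(r.gene_id)
            if hit is None:
                desc = "NSS"
            else:
                text, evalue = hit
                desc = "NSS" if evalue > nss_evalue else text
        return TopTableEntry(r.gene_id, r.base_mean, r.log2fc, r.padj, desc)

    ups = sorted(
        (r for r in eligible if r.gene_id in up),
        key=lambda r: (-r.log2fc, r.gene_id),
    )[:n]
    downs = sorted(
        (r for r in eligible if r.gene_id in down),
        key=lambda r: (r.log2fc, r.gene_id),
    )[:n]
    return [entry(r) for r in ups], [entry(r) for r in downs]


@dataclass(frozen=True)
class VolcanoRow:
    gene_id: str
    log2fc: float
    neg_log10_padj: float
    category: str  # significant | p_only | fc_only | ns


def volcano_prep(
    records: Sequence[DERecord],
    p_floor: float = P_FLOOR,
    padj_max: float = DEFAULT_PADJ_MAX,
    lfc_min: float = DEFAULT_LFC_MIN,
) -> List[VolcanoRow]:
    """Plot-ready rows with clamped p-values and the four point classes.

    Adjusted p-values below ``p_floor`` are set to the floor before the
    -log10 transform, so extreme points stay on the canvas.  Categories:
    significant (both thresholds passed), p_only, fc_only, ns.  Records
    without an adjusted p-value are omitted.
    """
    rows = []
    for r in records:
        if r.padj is None:
            continue
        p = max(r.padj, p_floor)
        sig_p = r.padj < padj_max
        sig_fc = abs(r.log2fc) > lfc_min
        category = (
            "significant" if sig_p and sig_fc
            else "p_only" if sig_p
            else "fc_only" if sig_fc
            else "ns"
        )
        rows.append(
            VolcanoRow(
                gene_id=r.gene_id,
                log2fc=r.log2fc,
                neg_log10_padj=-math.log10(p),
                category=category,
            )
        )
    return rows


def ranked_export(
    records: Sequence[DERecord],
    base_mean_min: float = 100.0,
) -> List[Tuple[str, float]]:
    """Two-column ranked list for enrichment tools.

    Genes at baseMean >= ``base_mean_min``, sorted by log2FC descending,
    ties broken by gene id.
    """
    rows = [
        (r.gene_id, r.log2fc) for r in records if r.base_mean >= base_mean_min
    ]
    rows.sort(key=lambda x: (-x[1], x[0]))
    return rows


def ranked_export_text(records: Sequence[DERecord],
                       base_mean_min: float = 100.0) -> str:
    return "".join(
        f"{gid}\t{lfc:g}\n" for gid, lfc in ranked_export(records, base_mean_min)
    )


def split_enrichment_directions(
    rows: Sequence[Mapping[str, object]],
    direction_key: str = "direction",
) -> Tuple[List[Mapping[str, object]], List[Mapping[str, object]]]:
    """Fold "both"-direction enrichment terms into the up and down lists.

    Terms skewed in both directions belong in both output lists; row
    order is preserved.
    """
    up_rows, down_rows = [], []
    for row in rows:
        direction = row[direction_key]
        if direction == "up":
            up_rows.append(row)
        elif direction == "down":
            down_rows.append(row)
        elif direction == "both":
            up_rows.append(row)
            down_rows.append(row)
        else:
            raise DEError(f"unknown direction label {direction!r}")
    return up_rows, down_rows
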
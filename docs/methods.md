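# Methods

## Problem and scope

`annotweave` updates a reference genome annotation (GTF) using assembled
RNA-seq transcripts as evidence. The pipeline has three stages —
classify, plan, apply — followed by accounting modules (assembly
statistics, merge distribution, gene-level BUSCO reconciliation,
differential-expression summaries). Everything upstream of the GTFs
(read alignment, assembly) and everything downstream of the DE table
(the negative-binomial model fit itself, functional enrichment) is out
of scope: those are consumed or produced as files, not recomputed.

## Data model and coordinates

Coordinates are GTF-style: 1-based, inclusive at both ends. A
transcript is an ordered chain of disjoint exons on one strand of one
sequence; its *intron chain* is the ordered list of (start, end) gaps
between consecutive exons. Transcript length is exonic length (summed
exon lengths), not genomic span — this is the length entering all
summary statistics. Strand `.` is permitted only on single-exon
transcripts (an intron chain is strand-dependent) and is treated as
compatible with either explicit strand wherever strands are compared.

On parsing, exon features are authoritative; gene and transcript header
lines are optional metadata that must agree with the exon-derived
extents (StringTie output, for instance, carries no gene lines).
Serialisation is deterministic and `parse(write(A)) == A` holds at
field-level equality for every valid annotation set.

## Classification ladder

Each evidence transcript gets exactly one class code; the ladder is
evaluated top-down and the first matching rule wins (EXACT,
SPANS_MULTIPLE, NOVEL_ISOFORM, CONTAINED, EXONIC_OVERLAP_ONLY,
OPPOSITE_STRAND, INTERGENIC — see the package docstrings for the exact
predicates). Notable choices:

* **Intron-chain equality ignores terminal exon ends.** Evidence rarely
  fixes transcription start/end sites; identity of introns is the
  robust invariant.
* **Single-exon equivalence threshold 0.8 reciprocal overlap**
  (`single_exon_min_overlap`, configurable). A conventional cutoff for
  single-exon transcript equivalence; there is no intron chain to
  compare.
* **SPANS_MULTIPLE outranks NOVEL_ISOFORM**: gene-joining evidence must
  be detected even when the spanning transcript also shares introns
  with one of the genes.
* **Overlap is counted in exonic bases**, never genomic span, so a
  transcript inside the long intron of an unrelated gene does not touch
  it.
* A consequence of the ladder order is that any multi-exon transcript
  whose chain is a contiguous sub-chain of a reference chain shares an
  intron and is therefore classified NOVEL_ISOFORM before the CONTAINED
  rule is reached; CONTAINED in practice captures single-exon
  transcripts lying inside a reference exon. This is deliberate: a
  sub-chain transcript *is* added as an isoform, a contained fragment is
  not.
* Ties (e.g. a single-exon transcript matching two reference
  transcripts equally) break lexicographically by transcript id, making
  classification independent of index construction order.

The indexed classifier (per-seqid/strand interval trees plus hash
indexes of intron chains and individual introns) is cross-checked by an
independent exhaustive all-pairs comparator (`annotweave.naive`) that
shares nothing with it but the data model.

## Update semantics

* **ADD_ISOFORM**: NOVEL_ISOFORM transcripts are inserted into their
  gene; the gene id and its annotation attributes are untouched, and
  the transcript is renamed `<gene_id>.tN` with N the lowest free
  index. The evidence never states how added isoforms should be named;
  a deterministic scheme is required and this one keeps the gene's
  namespace self-describing.
* **MERGE**: spanning results define edges between reference genes;
  connected components (union-find) become single merged genes. Only
  transitive closure explains observed joins of up to 11 neighbors when
  individual transcripts rarely span more than two loci. Subunit
  transcript ids are kept verbatim; joining evidence transcripts become
  new isoforms of the merged gene; subunit annotation texts are
  concatenated `;`-joined in ascending genomic start order (a
  deterministic convention).
* **NEW_GENE**: intergenic transcripts are clustered among themselves
  by same-strand exonic overlap (single linkage); each cluster becomes
  one gene. Single-exon intergenic transcripts shorter than
  `min_novel_single_exon_len` (default 200 nt, configurable) are
  discarded as fragment noise before clustering.
* **Discards**: EXACT, CONTAINED, EXONIC_OVERLAP_ONLY and
  OPPOSITE_STRAND evidence is dropped. In particular antisense overlap
  is *not* instantiated as a new gene: the update is conservative and
  no antisense rule is supported by the inputs it consumes.
* **Identifiers**: merged and novel genes draw from one sequential
  counter formatted `GBIG_NNNNNN` (prefix, width and starting offset
  configurable, default start 0). Ids already present in the reference
  are skipped, ids are monotone in allocation order (merges first, then
  novel genes, each in genomic order), and the counter errors out past
  its width rather than wrapping.

Two invariants are enforced by construction and verified by tests:
every reference transcript id appears exactly once in the output, and
on fixtures (where no other effects interfere) the gene count obeys
n_out = n_ref − Σ_k (k−1)·merges[k] + n_novel. The update is idempotent:
re-running it with its own output as reference plans zero actions,
because added isoforms, merged units and novel genes all re-classify as
EXACT and the rest is discarded again.

## BUSCO reconciliation

Transcript-mode BUSCO scores every transcript, so isoforms of one gene
hitting the same ortholog appear as "Duplicated". Reconciliation maps
each hit's sequence id to its gene: an ortholog whose Complete or
Duplicated hits fall in exactly one gene is complete-single, in two or
more genes complete-duplicated; otherwise any Fragmented hit makes it
fragmented, else missing. Complete outranks fragmented (standard BUSCO
precedence); no re-scoring of fragmented hits against the best isoform
is attempted. Percentages are reported half-up to two decimals over the
full ortholog set.

## Differential-expression summaries

The module consumes DESeq2-style output tables; it does not reimplement
the DE model or the Benjamini–Hochberg correction. Thresholds are
strict: significant means padj < 0.1 and |log2FC| > 0.6 (both
configurable). The source material describes this threshold
inconsistently in one place ("FDR was greater than 0.1"); the package
implements the `< 0.1` reading, which matches the same material's other
two statements of the rule. "Four-fold or greater" is the inclusive
|log2FC| ≥ 2. Records with NA adjusted p-values are excluded, matching
DESeq2's independent-filtering convention. The low-expression filter
for top-fold-change tables reads baseMean < 70; the ranked-list export
keeps baseMean ≥ 100, sorts by log2FC descending and breaks ties by
gene id. Volcano preparation clamps adjusted p-values at 10⁻¹⁰ before
the −log10 transform. Enrichment terms flagged as skewed in "both"
directions are copied into both the up and the down output lists.

Percentages in textual summaries print as integers unless the exact
ratio terminates after one decimal (e.g. 15/24 → 62.5%); rounding is
half-up throughout, computed on exact integer ratios to avoid float
artifacts.

## Synthetic fixtures

The generators produce every input with a planted truth log, so all
downstream modules are verifiable without external data.

* **Annotation pairs**: reference genes are laid left-to-right on a
  synthetic scaffold (`Scaffold1`), separated by gaps larger than any
  intron, so unrelated neighbors can never touch. Evidence is built
  class by class: exact copies with perturbed terminal exon ends, novel
  isoforms formed by dropping a donor chain's first exon, merge groups
  realised as chains of k−1 pairwise-spanning two-exon transcripts
  (deliberately exercising transitive closure), intergenic clusters of
  mutually overlapping transcripts, antisense two-exon overlaps, and
  sub-length single-exon fragments. Default exon counts 3–5, exon
  lengths 100–400 nt, intron lengths 60–300 nt — compact but
  structurally realistic for the update logic, which never depends on
  absolute scale. The `table2` scenario plants merge groups realising
  the observed neighbor-join distribution {2:1082, 3:233, 4:53, 5:27,
  6:9, 7:4, 11:1} (1,409 instances over 3,303 genes), or a ÷50 scaled
  version that preserves every k for fast tests.
* **BUSCO tables**: planted gene-level categories are realised as
  transcript-level rows, including isoform-level duplicate pairs within
  one gene that reconciliation must collapse back to single. The
  default plant is the 1,013-ortholog set with {939, 58, 9, 7}.
* **DE tables**: planted per-day significant sets (defaults: day 1
  263 up/173 down with 75 and 14 at ≥4-fold; day 3 218/71 with 131 and
  22; day 7 24/14 with 15 and 13), a planted cross-day overlap
  structure for the up sets (13 d1∩d3-only, 1 d1∩d7, 5 d3∩d7, 3 in all
  three) and disjoint down sets. Every planted value keeps a margin of
  at least 0.01 from each decision boundary (0.1, 0.6, 2.0), so
  strict-versus-inclusive semantics cannot blur the truth; boundary
  behaviour itself is tested by explicit cases. A non-significant
  background (default 1,200 genes per day) includes baseMean values on
  both sides of the 70 and 100 cutoffs and a few NA p-values.

What the fixtures do *not* emulate: read-level noise, soft-clipped or
misassembled exon boundaries, genes nested in introns, overlapping gene
models on the same strand, and expression counts drawn from a real
count model (log2FC/padj are planted directly). Passing tests therefore
demonstrate the correctness of the classification, closure, accounting
and threshold logic under clean evidence — not robustness to assembly
artifacts in real data.

## Numerical and degenerate-input choices

* Rounding is half-up everywhere a value is printed (two decimals for
  BUSCO percentages, one for transcripts-per-gene, integers for length
  means), computed with `decimal` on exact ratios.
* Empty annotation sets parse and serialise fine but refuse to be
  summarized; empty plans apply as the identity.
* An evidence transcript on a seqid absent from the reference is
  INTERGENIC, not an error.
* Merge components mixing explicit strands raise an error rather than
  silently inventing a strand.

## Known limitations

* The update rules are exactly the three stated actions; effects such
  as gene splitting, or novel loci being absorbed into merges, are not
  modelled. On real data the published gene totals need not be exactly
  recoverable from the stated counts alone; the package instead
  guarantees its gene-count law on its own outputs.
* The class-code alphabet omits some relationships a full GFFcompare
  run distinguishes (intronic containment, polymerase run-on classes);
  evidence in those configurations lands in the nearest coarser class.
* Gene-level BUSCO reconciliation uses status precedence only; it does
  not re-evaluate scores across isoforms.
* The acceptance script runs the full-scale merge scenario (~3,300
  genes, ~1,900 spanning transcripts) and 25 randomized moderate
  scenarios; both complete in seconds on one CPU.
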
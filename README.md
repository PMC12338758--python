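# annotweave

Evidence-based updating of a draft-genome annotation from assembled
RNA-seq transcripts, with the downstream accounting that goes with it.

Draft-genome annotations of non-model organisms — the motivating case is
the Mediterranean field cricket *Gryllus bimaculatus*, whose prothoracic
ganglion shows unusual adult neuronal plasticity after deafferentation —
are typically incomplete: genes are missing, isoforms are missing, and
single transcription units are sometimes annotated as several separate
genes. Aligned RNA-seq data assembled into transcripts (e.g. by
StringTie) carries the evidence needed to repair all three defects.
`annotweave` consumes a reference GTF and an evidence GTF and produces an
updated annotation plus the summaries an annotation-update study reports.

## Method

Every evidence transcript *t* is classified against the reference by a
fixed decision ladder (first match wins), where "touching" a gene means
same-strand exonic overlap:

1. **EXACT** — *t*'s intron chain is identical to a reference
   transcript's chain (terminal exon ends are ignored: RNA-seq evidence
   rarely pins TSS/TES); single-exon transcripts match by reciprocal
   overlap ≥ 0.8 with a single-exon reference transcript.
2. **SPANS_MULTIPLE** — *t* touches ≥ 2 reference genes: evidence that
   neighboring annotated loci are components of one transcription unit.
3. **NOVEL_ISOFORM** — *t* shares ≥ 1 intron (both boundaries) with
   exactly one gene but no full chain.
4. **CONTAINED** — *t*'s chain is a contiguous sub-chain of a reference
   chain, or a single-exon *t* lies inside one reference exon.
5. **EXONIC_OVERLAP_ONLY** / 6. **OPPOSITE_STRAND** / 7. **INTERGENIC**.

The update then:

* adds each NOVEL_ISOFORM to its gene (gene id and annotation preserved,
  transcript renamed `<gene_id>.tN`);
* treats SPANS_MULTIPLE results as edges between reference genes and
  merges each connected component (union-find closure) into one gene
  with a fresh sequential id (`GBIG_NNNNNN`), keeping all subunit
  transcript ids verbatim — closure is what lets chained pairwise
  evidence join up to 11 neighbors even though no single read spans 11
  loci;
* clusters INTERGENIC transcripts by mutual exon overlap into novel
  genes, discarding single-exon fragments shorter than 200 nt;
* discards exact, contained, antisense and overlap-only evidence — the
  update instantiates nothing the evidence does not positively support.

Around the update, the package computes assembly summary statistics
(gene/transcript counts, exonic length statistics), the merge-size
distribution table, gene-level reconciliation of transcript-mode BUSCO
results (isoform-level "duplications" within one gene collapse back to
complete-single), and threshold-based differential-expression summaries:
significance at adjusted *p* < 0.1 and |log2FC| > 0.6, four-fold bins
(|log2FC| ≥ 2), three-timepoint Venn partitions, top-fold-change tables
(baseMean ≥ 70), volcano-plot preparation with *p*-values clamped at
10⁻¹⁰, and a ranked-list export (baseMean ≥ 100) for enrichment tools.

## Worked example

Generate a synthetic fixture bundle (reference + evidence GTFs with a
known planted truth), then run the update:

```sh
$ annotweave fixtures --scenario default --seed 4 -o demo/
$ annotweave stats demo/ref.gtf
N(Genes)        30
N(Transcripts)  34
Average transcripts per gene    1.1
Max transcripts per gene        2
Average transcript length       942
Median transcript length        925
Max transcript length   1491

$ annotweave update demo/ref.gtf demo/evidence.gtf -o demo/updated.gtf \
      --report demo/report.json --merge-table demo/merge.tsv
added 6 isoforms to 6 genes; 2 merges; 3 novel genes; 9 discarded

$ cat demo/merge.tsv
# of joined neighbors   # of instances
2       1
3       1
total   2
```

The report says the evidence added 6 isoforms to 6 existing genes,
joined one pair and one triple of neighboring genes into two merged
genes, created 3 novel genes, and discarded 9 transcripts (exact
duplicates, antisense overlaps and sub-length fragments). Gene counts
obey n_out = n_ref − Σ(k−1)·merges + n_novel = 30 − 3 + 3 = 30.

BUSCO reconciliation and DE summaries on the same bundle:

```sh
$ annotweave busco-genes demo/busco_full_table.tsv demo/updated.gtf
category        count   %
complete-total  12      80.00
complete-single 10      66.67
complete-duplicated     2       13.33
fragmented      2       13.33
missing 1       6.67
total   15

$ annotweave de-summary demo/de_d1.tsv | head -2
up      263     up_ge4fold      75      29%
down    173     down_ge4fold    14      8%
```

At this timepoint 263 genes are significantly up- and 173 down-regulated;
75/263 (29%) of the upregulated and 14/173 (8%) of the downregulated
changed four-fold or more.

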
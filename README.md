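# peakforge

Post-alignment analysis of developmental ATAC-Seq/RNA-Seq designs:
consensus open-chromatin peaks, ENCODE-style library QC, count
normalization and ordination, negative-binomial differential testing,
genomic-feature annotation, and a signed-distance overlay of peaks onto
differentially expressed genes. The package was built around a study of
developing pig skeletal muscle — open chromatin profiled in
semitendinosus muscle from 24 piglets spanning five developmental
stages (gestational day 45/60/90, postnatal weeks 1 and 6) and three
within-litter size classes — but every stage is generic: peak calls,
fragments, an annotation and a design table go in; tables come out.

A first-class synthetic-data module generates all inputs with the
statistical structure the analysis assumes (tri-modal fragment sizes,
TSS-enriched placement, NB counts with planted timepoint and
size-class effects over an unbalanced litter design), so the entire
pipeline runs and is tested without any sequencing data.

## The statistics at the core

**Consensus peaks.** Per-sample calls within 10 bp of one another are
transitively merged; each merged peak carries a *support* value (number
of distinct contributing samples) and peaks with support < 3 are
dropped.

**Differential accessibility.** For each consensus peak, counts are
modelled as NB(μ, α) with log link, log median-of-ratios normalization
factors as offsets and a moment-estimated, trend-shrunk dispersion.
Nested fits of `~ size + time` against `~ size` give a likelihood-ratio
statistic referred to χ² (df = 4); p-values are Benjamini–Hochberg
corrected at FDR 10% and peaks must additionally clear |log2FC| > 2.
Day-90 differential expression tests `~ size` against intercept-only
with the small size class as reference.

**Ordination.** Counts are normalized as
`log2(count / library size × 1e8 + 1)`; Manhattan distances between
samples feed a Kruskal non-metric MDS (stress-1 with isotonic
disparities, Torgerson initialization, Guttman updates). Expression is
ordinated by PCA.

**QC.** TSS enrichment score (max ratio of 100-bp window depth to
flank-end depth over ±1 kb around TSSs), FRiP, NRF/PBC library
complexity, NFR score, fragment-size distribution, binned-coverage
correlation.

**Overlay.** Every (gene, peak) pair within ±10 kb is reported with a
signed start-distance — positive within the gene or its 10-kb upstream
region, negative within 10 kb past the 3′ end — plus the peak's
size-class specificity (shared / small-only / average-only /
large-only) and the gene's DE status.

## Worked example

Run the full synthetic analysis end to end:

```sh
peakforge run --out demo --seed 1
```

which logs each stage and prints the surviving counts:

```json
{
 "input_peak_calls": 3760,
 "raw_fragments": 192000,
 "filtered_fragments": 173089,
 "merged_peaks": 244,
 "consensus_peaks": 174,
 "tested_peaks": 174,
 "significant_peaks": 5,
 "significant_genes": 7,
 "overlay_records": 216
}
```

Reading the numbers: 24 samples contributed 3760 peak calls, which
merge into 244 peaks, of which 174 are supported by ≥ 3 samples (150
planted core peaks plus 3 × 8 day-90 size-specific peaks; the private
noise peaks fail the support filter). Of 192 000 simulated fragments,
173 089 survive the mapq/flag/MT filter. The NB-LRT finds 5
differential peaks at FDR 10% and |log2FC| > 2 — recovered from
fragment counting alone, where background fragments dilute the planted
fold changes — and the day-90 expression test recovers 7 size-affected
genes. `demo/qc_report.tsv` holds the per-library QC, e.g.:

```
sample          n_fragments  tss_es   frip    nrf   pbc1    pbc2  nfr_score
1WK_large_L7           7214  10.373  0.487  0.965  0.965  28.338      1.662
1WK_small_L7           7204  11.852  0.480  0.964  0.963  26.756      1.650
6WK_average_L8         7233  10.583  0.474  0.965  0.965  28.176      1.537
```

A TSS enrichment score ≈ 10 means the densest 100-bp window near TSSs
is ten times deeper than the flank ends — a strongly enriched library;
FRiP ≈ 0.48 says half the fragments fall in called peaks; NRF ≈ 0.96
with PBC1 ≈ 0.96 indicates low duplication. `demo/overlay.tsv` lists
each DE gene's nearby peaks with signed distances and size
specificity, and `demo/manifest.json` records checksums for every
artifact.

The same stages are available as subcommands on real files
(`peakforge consensus`, `qc`, `annotate`, `ordinate`, `diffpeaks`,
`diffgenes`, `overlay`, `sizesplit`) and as plain library functions.

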
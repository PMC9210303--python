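# Methods

`peakforge` implements the post-alignment analysis of a developmental
ATAC-Seq/RNA-Seq design: per-sample open-chromatin peak calls and
filtered fragments go in; a support-filtered consensus peak set,
library QC metrics, sample ordinations, negative-binomial differential
tests and a peak-to-gene overlay come out. A synthetic-data module
generates all inputs with the statistical structure the analysis
assumes, so the whole pipeline is testable without sequencing data.

## Consensus peaks

Per-sample peak calls are merged by transitive closure of the relation
"gap ≤ `merge_gap`", where the gap between two same-chromosome
intervals is `next.start − prev.end` (≤ 0 for overlapping or book-ended
pairs). The default `merge_gap` of 10 bp matches the common
`bedtools merge -d 10` idiom. Each merged peak carries a *support*
value: the number of distinct samples contributing at least one call
(a sample contributing two calls to one merged peak counts once).
Peaks with support below `min_support` (default 3 of 24 samples) are
removed; the survivors are the consensus set used for counting and
testing. Consequences of the construction, verified by property tests:
merging is idempotent, invariant to input order, conserves the total
number of member calls, and leaves consecutive consensus peaks more
than `merge_gap` apart.

Fragment counting assigns a fragment to every consensus peak it
overlaps by ≥ 1 bp, unstranded. Because consensus peaks are disjoint, a
fragment can touch at most a short contiguous run of peaks; a fragment
longer than the inter-peak gap may legitimately count toward two peaks,
and the implementation follows the ≥ 1 bp-overlap definition rather
than forcing uniqueness. Per-sample library size is the total number of
filtered fragments, in or out of peaks.

### Size-class sharing

For the day-90 comparison, per-size-class peak sets are partitioned by
cross-class overlap: a peak is *shared* when it overlaps ≥ 1 bp of a
peak in every other class, *specific* when it overlaps none, and
*partial* otherwise. Partial peaks are reported but excluded from both
the shared and specific sets, since calling them either would
overstate the evidence.

## QC metrics

Fragments are filtered before any metric is computed: mapping quality
≥ 10, proper-pair flag set, none of the unmapped / mate-unmapped /
QC-fail / duplicate bits set (the `samtools -f2 -q10 -F1548`
combination), and mitochondrial fragments removed.

- **Fragment-size distribution** — histogram of fragment lengths with
  the `log2(count / max count)` density transform; lengths are also
  binned into nucleosome-free (< 100 bp), mono-nucleosome (180–247 bp)
  and di-nucleosome (315–473 bp) bands following ENCODE convention.
- **TSS enrichment score** — the ±1 kb region around each TSS is tiled
  into twenty 100-bp windows; fragment-overlap depth is aggregated over
  all TSSs (minus-strand profiles reversed), each window's mean depth
  is divided by the mean depth of the two outermost windows, and the
  score is the maximum window ratio. Uniform coverage gives exactly 1.
  Depth is fragment coverage, not cut-site counts; a cut-site variant
  would sharpen the peak but the depth form is the one implemented.
- **FRiP** — fraction of filtered fragments overlapping any peak by
  ≥ 1 bp.
- **NRF / PBC1 / PBC2** — computed over distinct (chrom, start, end)
  fragment triples (the natural notion for a paired-end library, rather
  than 5′ ends): NRF = distinct/total, PBC1 = (positions seen
  once)/distinct, PBC2 = (seen once)/(seen twice), reported as +inf
  with a flag when no position is seen twice.
- **NFR score** — log2(nucleosome-free count / mono-nucleosome count).
  The band bounds are the ENCODE ones above; the score is undefined
  (an error) when either band is empty.
- **Binned coverage correlation** — the genome is tiled into 100-bp
  bins, fragments assigned to the bin containing their midpoint, and
  Pearson correlation computed between per-sample bin-count vectors.

## Ordination

Raw counts are normalized as

    normalized = log2(count / library_size * 1e8 + 1)

which is monotone in the count and maps zero to zero. Sample-by-sample
Manhattan distances over the normalized consensus-peak matrix feed a
non-metric MDS in Kruskal's formulation: find coordinates whose
inter-point distances D are close to a monotone transform of the input
dissimilarities, measured by stress-1

    stress = sqrt( Σ (D_ij − d̂_ij)² / Σ D_ij² )

with d̂ the isotonic regression of D on the dissimilarity order
(pair-adjacent-violators, ties averaged). The configuration starts from
classical (Torgerson) scaling and alternates the isotonic fit with a
Guttman-transform update; an update that would raise stress is
discarded and iteration stops, so the recorded stress sequence is
non-increasing by construction. Defaults: k = 3 components (to expose
the component-1–3 views), `max_iter` = 200, `tol` = 1e-6. No extra
centering or scaling is applied beyond the count normalization.
Expression matrices are ordinated by centered (unscaled) SVD-based PCA
with variance shares summing to one.

## Differential testing

Per-sample normalization factors are median-of-ratios: the median over
all-positive features of each sample's count divided by the feature's
geometric mean. Dispersion is estimated per feature by moments on
normalized counts — pooled within-cell variance s² over design cells
with ≥ 2 replicates, overall mean μ, raw estimate
max(0, (s² − μ)/μ²) — then shrunk 50% toward a fitted hyperbolic
mean-dispersion trend a₀ + a₁/μ and floored at 1e-8. This is a
deliberately simple stand-in for empirical-Bayes dispersion machinery;
the target is error-rate control, not numerical identity with any
reference tool.

Each feature is fitted under two nested NB log-link GLMs with the log
normalization factors as offsets and dispersion held fixed: the full
design `~ size + time` and the reduced design `~ size` (treatment
coding, small size and the earliest timepoint as references). Fitting
is batched Fisher scoring with per-feature step halving; because the
NB log-likelihood with fixed dispersion is concave in the
coefficients, the damped iteration converges to the maximum-likelihood
estimate (verified against an independent GLM implementation to ~1e-6).
The likelihood-ratio statistic 2(ℓ_full − ℓ_reduced) is referred to a
chi-square with degrees of freedom equal to the parameter-count
difference. Features whose fits do not converge get a missing p-value
and do not count toward the multiple-testing denominator.
Benjamini–Hochberg step-up correction is applied at FDR 10%, and
differential *peaks* additionally require the largest absolute log2
fold change across timepoint contrasts to exceed 2 (fold changes are
unshrunk MLEs; no shrinkage estimator is applied, and reported values
are labelled as such). Day-90 differential *expression* tests
`~ size` against an intercept-only model on the day-90 samples alone,
reporting large-vs-small and average-vs-small log2 fold changes (small
is the denominator) plus the derived average-vs-large contrast, with a
|log2FC| ≥ 0.1 reporting flag.

Litter is recorded in the design table but not included in the default
design (the two candidate specifications disagree in the source
material); `nb_lrt` accepts arbitrary factor-term lists, so
`full=("size", "timepoint", "litter")` is available when litter should
be a fixed covariate.

### Calibration notes

- Given the generating dispersion, null LRT p-values are uniform (KS
  p ≈ 0.7 at 2000 features) and the statistic matches a Poisson-GLM
  oracle in the dispersion → 0 limit.
- With *estimated* dispersion, the unbalanced 24-sample design leaves
  only ~10 within-cell residual degrees of freedom, and plug-in
  dispersion noise inflates the 5% type-I rate to roughly 4–8%
  depending on seed. The composed pipeline still controls FDR with a
  wide margin (mean empirical FDP ≈ 0.2% at the nominal 10% under the
  mixed simulation) because BH and the fold-change filter absorb the
  residual miscalibration.
- Chi-square asymptotics degrade for features with very low counts
  (means below ~10); such features test conservative. No independent
  filtering is applied by default.

## Annotation and overlay

Each peak is assigned exactly one feature category by a fixed
precedence anchored at the peak midpoint (the anchor is configurable;
the choice of midpoint is a documented default, not derivable from the
category definitions): promoter windows at ≤ 1 / 1–2 / 2–3 kb absolute
distance from the nearest TSS, then 5′ UTR, 3′ UTR, first exon, other
exon, first intron, other intron, downstream ≤ 3 kb past the 3′ end,
else distal intergenic. Category frequencies are reported as percent of
total with a 3-significant-figure printed form. A documented surjection
collapses the fine categories onto the coarser vocabulary used for
differential-peak summaries: both ≤ 2 kb promoter windows → Promoter;
the 2–3 kb window and downstream → Proximal; first exon → CDS; other
exon → Exonic; introns → Intronic; distal → Intergenic.

The overlay links peaks to genes within a ±10-kb window through a
signed start-distance: positive when the peak's 5′-most boundary lies
within the gene body or its 10-kb upstream region, negative when it
lies within 10 kb past the 3′ end, undefined (no record) outside. The
magnitude is the strand-aware distance from the gene's 5′ end, so
|value| ≤ gene length + 10 kb, and the definition is strand-mirror
symmetric (property-tested). One record is emitted per (gene, in-window
peak) pair, carrying the peak's size-class specificity and the gene's
differential-expression flag.

## Synthetic data

The generator emulates the study conditions end to end:

- **Design** — 24 samples over five stages (gestational day 45/60/90,
  postnatal week 1/6) × three size classes (small/average/large), with
  the deliberate imbalance of a litter-based study: complete litters
  only at the earliest stages, four litters at day 90 (11 samples), two
  postnatal partial litters.
- **Genome/annotation** — two 1-Mb autosomes plus a 16-kb MT (so the
  mitochondrial filter is exercisable); 60 non-overlapping genes of
  3–15 kb with 2–6 exons, terminal-exon UTRs, one TSS per gene at the
  strand-aware 5′ end.
- **Fragments** — lengths from a three-component normal mixture at
  50/180/350 bp (weights 0.50/0.32/0.18), reproducing the
  nucleosome-free / mono / di banding; 40% of fragments pile up
  triangularly within ±1 kb of TSSs, 30% fall inside planted peaks, 2%
  on MT, the rest uniform; 8% fail the quality filter (low mapq,
  duplicate flag, or broken pair in equal shares) and 4% are unmarked
  position duplicates so NRF/PBC have signal.
- **Peak calls** — 150 core peaks present in every sample with ≤ 20 bp
  boundary jitter, 55% placed within 1 kb of a TSS; eight size-specific
  peaks per class, present only in day-90 samples of that class; three
  private noise peaks per sample. All planted peaks are separated by
  more than merge_gap + 2·jitter, so consensus construction recovers
  the planted truth exactly.
- **Counts** — NB with dispersion 0.1 and log-normal library factors
  (sd 0.3, forcing non-trivial normalization). 10% of peaks carry a
  time effect of |log2FC| = 2.5 applied at one randomly chosen "active"
  timepoint per peak (sign random). A per-peak active timepoint, rather
  than a monotone trend, gives every developmental stage its own marker
  peaks — the structure that makes timepoints separate in ordination —
  while keeping the maximum contrast equal to the nominal effect size.
  Expression matrices instead plant size-class effects (large shifted
  by the full effect, average by half) on 10% of genes.

Everything is a deterministic function of the configuration seed, with
independent substreams per output so regenerating one artifact never
perturbs another.

What the generator does *not* emulate: sequence content, GC or
transposase insertion bias, peak-calling errors, correlated
fragment placement beyond the TSS/peak components, litter random
effects, or dispersion that varies with mean beyond the planted
constant. Passing tests therefore demonstrate the correctness and
calibration of the analysis under its own assumptions, not robustness
to the biases of real libraries.

## Problem sizes

Defaults are chosen so a full synthetic run (24 samples × 8000
fragments, 174 consensus peaks) completes in about one second and the
20-replicate FDR study (2000 peaks × 24 samples per replicate) in a few
seconds, while keeping every estimate comfortably away from
small-sample degeneracy.

## Known limitations

- The moment dispersion estimator is noisy at this replication level;
  see the calibration notes. It is also mean-biased upward for features
  whose expression shifts within a design cell not represented in the
  grouping terms.
- PBC2 is undefined (reported +inf) for libraries with no
  position seen exactly twice — common at toy depths.
- The NMDS stops rather than restarts when a Guttman step would
  increase stress-1; on pathological inputs this can return a local
  minimum. Classical-scaling initialization makes this rare in
  practice, and two-seed runs agree to < 1% RMS after Procrustes
  alignment on well-conditioned inputs.
- `signed_start_distance` keys on the peak's 5′-most boundary only; a
  peak overlapping a gene whose 5′ boundary lies outside the ±10-kb
  window produces no record.
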
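# Methods

## Problem and model

Targeted enrichment (whole-exome capture, gene panels, ChIP) is imperfect:
a large fraction of sequenced fragments — often half — maps outside the
enriched regions.  These off-target reads are, to good approximation,
sampled uniformly per base pair with intensity proportional to the local
DNA copy number.  After the enriched territory is identified and masked,
the remaining reads therefore behave like a low-coverage whole-genome
sequencing experiment, and standard read-depth copy-number machinery
applies genome-wide, including to gene-poor regions that exon-count
methods cannot see.

The per-bin model: for a bin of width `L_b` with `x` bp masked as
enrichment peaks, the observed read-start count `N` has expectation

    E[N] ∝ (L_b − x) · c · b(gc, map)

where `c` is the local copy number and `b(·)` a smooth technical bias in
GC content and mappability.  The pipeline inverts this step by step:

1. **Read filtering** — keep primary, mapped, properly paired,
   non-duplicate reads with mapping quality ≥ 37; drop mitochondrial
   reads.  Secondary/supplementary alignments are never counted.
2. **Peak calling and removal** — enrichment peaks are called in the
   matched reference sample (or, without a reference, in the sample
   itself) with a single-sample local-Poisson caller: reads are extended
   to the expected fragment length d (default 200 bp) from their 5' end;
   a base is enrichment-candidate when its extended coverage `k` has
   Poisson tail `P(X ≥ k; λ_local) <` cutoff (default 1e-5), with
   `λ_local` the maximum of the genome-wide rate and rates in local
   windows (defaults 5 and 10 kb); candidates merge within 100 bp, peaks
   narrower than 50 bp are dropped.  Reads overlapping a peak by ≥ 1 bp
   are discarded in sample *and* reference.  A precomputed peak BED may
   replace the internal caller.
3. **Compensated depth of coverage** — read-start counts in consecutive
   bins (default 20 kb; 100 kb recommended for small gene panels), scaled
   by `L_b / (L_b − x)`.  Bins with less than 10% effective width become
   missing rather than explode.
4. **Loess corrections** — a tricube-weighted local polynomial
   (degree 2, span 0.75) of counts against GC, then against mappability;
   each bin is rescaled by `median / m(c_i)`, which flattens the trend and
   preserves the profile median.  The fit is robust: Tukey-bisquare
   reweighting (3 iterations), plus a two-pass residual trim — bins whose
   residuals from a first fit fall outside the central [0.1, 0.9]
   quantiles are dropped before refitting.  Copy-number-aberrant bins are
   level shifts a smooth covariate curve cannot explain, so they land in
   the residual tails and do not bend the technical trend, while a
   genuine strong bias (small residuals everywhere) survives trimming and
   is corrected in full.  This is the standard defence used by read-depth
   correctors; without it a large CNA that happens to occupy a narrow
   covariate stratum is partially absorbed into the "bias" and subtracted
   from itself.
5. **Filters and normalisation** — bins are dropped for low mappability
   (< 0.2), any blacklist overlap, or zero/missing counts; values are
   divided by the median over usable *autosomal* bins and log2-scaled, so
   sex-chromosome copy state never shifts the baseline.
6. **Relative profiles** — with a matched reference, the reference's
   normalised log2 is subtracted bin-wise; identical inputs give exactly
   zero.  Without a reference the sample's own median is the baseline
   ("absolute" mode) — workable here precisely because off-target
   coverage does not depend on bait efficiency.
7. **Segmentation (CBS)** — within each chromosome, the circular arc
   maximising the pooled-variance two-sample t statistic is found by
   exhaustive enumeration (the arc and its complement describe the same
   partition, so linear arcs suffice); the split is accepted when a
   seeded permutation p-value is below alpha (default 0.01) and recursion
   continues into the pieces.  Permutations run in batches with an exact
   one-sided early stop: once the exceedance count guarantees
   p ≥ alpha the remaining permutations cannot change the decision.
   Ties in the arc statistic resolve to the smaller (length, start)
   after canonicalising end-touching arcs against their complements.

### Segmentation guards

Bin counts are overdispersed — both mates of a proper pair are counted,
roughly doubling the Poisson variance — so occasional few-bin noise
clusters reach arc-maximum significance even though they are not copy
number.  Two standard guards handle this, both configurable:

* `min_width = 5` bins: the smallest arc considered for a split, at the
  upper end of the range classic CBS implementations allow.
* `undo_sd = 2.5`: adjacent segments whose means differ by less than
  2.5 × the per-bin noise SD (diff-based MAD estimate) are merged, the
  classic SD-undo pass.  The threshold sits between the amplitude a
  *detectable* short noise cluster can have (≈ 2.1–2.25 SD for 4–5-bin
  arcs at the arc-max critical value) and the smallest jumps the
  simulation study asks to recover (0.58 at SD 0.2 ≈ 2.9 SD, 1.0 at
  SD 0.26 ≈ 3.8 SD), so flukes merge and real aberrations survive.
  For very noisy substrates (the on-target comparator, where per-region
  SD can approach the jump size) the undo pass merges real jumps too —
  the known over/under-segmentation weakness of exon-count data; disable
  it (`undo_sd = 0`) to see the raw segmentation.

## Evaluation statistics

* **Diff-based MAD**: `1.4826 · median(|d − median(d)|) / √2` over lag-1
  differences `d` of consecutive bin values — a per-bin noise SD estimate
  unaffected by piecewise-constant signal (the √2 undoes the variance
  doubling of differencing).
* **SNR**: |segment mean| of the segment with the largest overlap with a
  region of interest, divided by the profile MAD.
* **Array pseudo-counts**: probe intensities mapped onto the bin grid,
  either the probe nearest the bin centre (ties to the lower coordinate)
  or the mean of in-bin probes (missing when none), for cross-platform
  comparison on a common grid.
* **Weighted concordance** of two segmentations: over the intersection
  regions `r` (length `w_r`, means `a_r`, `b_r`),
  `√(Σ w_r (a_r−b_r)² / Σ w_r)` and the `w_r`-frequency-weighted Pearson
  correlation.
* **Random-placement overlap**: the observed fraction of query intervals
  hitting an annotation is compared with seeded simulations that re-place
  the same interval lengths uniformly (chromosome chosen proportional to
  placeable length); the empirical p uses the +1 correction.

## The synthetic capture study

The generator emulates the data regime the method is built for, with
known truth.  Defaults (the study conditions; all per-seed deterministic
via split `SeedSequence` streams for genome, baits, and each sample):

| parameter | default | meaning |
| --- | --- | --- |
| chromosomes | 2 × 10 Mb | small diploid genome |
| GC landscape | 0.3 → 0.6 drift + 0.04 sine, 1 Mb period | monotone chromosome-scale trend plus isochore-like variation, so one CNA never owns a GC stratum |
| baits | every 10 kb, 120 bp | regular capture tiling |
| bait efficiency | lognormal sd 0.5 (shared) × sd 0.3 (per sample) | heterogeneous capture, imperfectly reproducible between libraries |
| θ_on | 30 pairs/bait/copy | on-target intensity |
| θ_off | 3·10⁻³ pairs/bp/copy | ≈ 240 off-target starts per 20 kb bin at CN 2; off-target fraction ≈ ⅓ of retained reads, within the 40–60% capture-efficiency regime |
| reads | 2 × 100 bp pairs, 300 bp fragments | proper pairs, mapq 60, 5% at mapq 20 |
| truth | CN 4 on 30–50% of chr1, CN 1 on 40–60% of chr2 | one gain, one loss, diploid elsewhere |

Reads are emitted as already-aligned, sorted, indexed BAM records; no
sequence-level realism (the FASTA matters only through GC).  An optional
`gc_bias_exponent` multiplies the off-target rate by
`exp(β(gc − 0.5))` of the local 10 kb window to exercise the loess
correction.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about real data: alignment artefacts and mappability
structure, FFPE damage, realistic insert-size distributions, subclonal
or non-integer copy states, genome-scale segmental duplication, and the
CNV blacklist problem (the blacklist path is exercised only with
user-supplied BEDs).

## Numerical choices and degenerate inputs

* Missing values are NaN throughout and propagate; usability flags gate
  every statistic.
* Compensation raises on `x > L_b` (an upstream accounting bug), returns
  missing at ≥ 90% masking.
* Loess requires ≥ 30 fit pairs and errors otherwise (advice: larger
  bins); non-positive fitted values leave a bin missing.
* Noiseless CBS splits (zero within-group variance, nonzero mean
  difference) get an infinite statistic and are always accepted.
* Chromosome-name dialects ("chr1" vs "1") are resolved by prefix at
  ingest; any deeper mismatch is an error naming the chromosome, never a
  silent drop.
* The whole pipeline is byte-reproducible for a fixed configuration and
  inputs; every stochastic step takes an explicit seed.

## Problem sizes

End-to-end checks run the default two-chromosome 10 Mb study
(1,000 bins, ≈ 3·10⁵ read records per sample); unit-level pipeline tests
use 2 × 3 Mb genomes.  These sizes keep a full simulated study and its
segmentation in the low minutes on one CPU while leaving per-bin counts,
noise levels, and aberration sizes (in bins) representative of 20 kb-bin
exome profiles.

## Known limitations

* The peak caller is a simplified single-sample local-Poisson model —
  no fragment-size model estimation, duplicate-tag correction, or FDR —
  and is not a drop-in reproduction of dedicated ChIP-seq callers; a
  peak BED from any external caller can be substituted.
* The permutation null for CBS assumes exchangeable bins within a
  segment; long-range autocorrelation (e.g. residual waviness) inflates
  split rates.
* SD-undo is scale-blind: on substrates whose per-bin noise approaches
  the jump size it merges real events (see above).
* Absolute mode centres on the autosomal median; a genome that is
  mostly aberrant shifts that baseline, as for any self-normalised
  method.
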
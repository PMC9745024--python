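# Methods

## The fragment-distance representation

Conventional low-coverage cfDNA aneuploidy callers reduce each genomic
bin to a single fragment count (FC). This package instead works with
the *spacing* of fragments. Single-end reads report strand-dependent
coordinates, so positions are first harmonised: a forward read's
position is its leftmost aligned base plus 80 bp; a reverse read's is
its rightmost aligned base minus 80 bp. The fragment distance (FD) is
then the difference between adjacent shifted positions along a
chromosome — successive differences of the sorted positions. Each
distance is attributed to the 1-Mb bin containing the left member of
its pair (so every distance lands in exactly one bin), and per bin the
FD sample is summarised by its mean, median and IQR alongside FC.

Under a locally homogeneous fragmentation process, FD behaves like the
gaps of a Poisson point process: more fragments mean smaller distances
(mean gap ≈ covered length / n), so a trisomic chromosome at fetal
fraction *f*, whose fragment intensity rises by 1 + *f*/2, shows
distances shrunk by ≈ 1/(1 + *f*/2). Unlike FC, FD yields a
distribution per bin, so mean, median and IQR give three partially
independent views that an ensemble can combine; bins with equal median
FD but different FC exist, so the two features are not redundant.

## Bin grid and exclusion rules

Chromosomes are tiled with non-overlapping 1-Mb bins. A bin is
excluded when it (a) overlaps a masked interval (centromere/telomere or
other problematic region) by at least 1 bp, (b) has mappability ≤ 80 %,
or (c) has GC ≤ 30 % or > 50 % (boundaries per the inclusive/exclusive
reading of the rules; GC exactly 50 is retained, mappability exactly 80
is excluded). Chromosome tails shorter than the bin width are dropped
outright: a partial bin would mix a different expected fragment count
into the FD statistics. Input reads are filtered to primary alignments
with MAPQ ≥ 60 and no duplicate flag.

## TRS images

For one sample and one target chromosome (TC ∈ {chr13, chr18, chr21}):

1. **Control selection (ICC).** On a euploid reference cohort, each
   eligible autosome (not a trisomy target, not a sex chromosome) is
   scored by ordinary least squares of the target's reciprocal
   chromosome-level median FD on the candidate's, across samples; the
   three candidates with the highest −log10(MSE) become the internal
   control chromosomes, ordered best first. A numerically perfect fit
   scores +∞; ties break by chromosome order.
2. **Normalisation.** The sample's *global median* is the genome-wide
   median of per-bin FD medians over retained, usable bins; every
   per-bin representative value (mean, median and IQR alike) is divided
   by it. This single normaliser is deliberately shared across the
   three representatives — it makes all three sequences depth-free
   while preserving their relative scales. (A per-representative
   normaliser is a defensible alternative; the shared one is the
   simpler contract and is fixed here.)
3. **Trimming.** Per chromosome and per representative, the lowest and
   highest floor(0.10·n) bins by normalised value are removed, genomic
   order of survivors preserved. Trimming is per chromosome, not
   pooled, so each segment loses at most 20 % of its bins. This step
   is what blunts focal maternal CNVs: a multi-bin CNV produces extreme
   normalised values that fall inside the trimmed tails.
4. **Rasterisation.** The six segments ICC₁, TC, ICC₂, TC, ICC₃, TC
   are concatenated (TC at positions 2, 4, 6), the bin index rescaled
   to 400 columns, and the values drawn as a 1-px Bresenham polyline
   (intensity 1 on background 0) into a 200×400 matrix. The y-axis is
   a *fixed* affine map from [0.5, 1.5] (values clipped) to rows
   199→0. Per-image min–max scaling would erase the trisomy signal —
   the informative feature is precisely the vertical offset of the TC
   band relative to the ICC band — so a fixed range is essential. The
   rasteriser writes the matrix directly (no plotting canvas, no
   anti-aliasing) so images are bit-reproducible; 200 ppi is metadata
   only. The direction of the effect is not assumed by the pipeline:
   trisomy lowers TC distances, the classifier learns the offset either
   way.

## Classifiers and ensemble

Each (target, representative) pair gets a small binary CNN trained on
the TRS images. The engine is a pure-numpy implementation (im2col
convolutions, max pooling, dense layers, Adam, weighted binary
cross-entropy): at these image sizes and cohort sizes a small network
trains in seconds on one CPU, and a from-scratch implementation keeps
training bit-reproducible run-to-run from a single integer seed.

Default architecture: fixed 4×4 average pooling at the input
(200×400 → 50×100; the polyline survives coarse resolution), two
conv+ReLU+maxpool blocks (8 then 16 filters of 3×3), one hidden dense
layer of 32 units with dropout 0.25, and a sigmoid head. Learning rate
3·10⁻³, batch 32, up to 40–60 epochs with early stopping on validation
loss (patience 6–8). This fixed small architecture replaces a
large-scale Bayesian hyperparameter search, which is out of proportion
to the quantity being exercised here (the FD/TRS representation, not
architecture search); a small optional random-search mode
(`classifier.random_search`) exists for users who want it.

Cross-validation uses five folds, stratified by label (severe class
imbalance — trisomy-13-scale positives — would otherwise leave folds
without positives, which raises an instructive error). Within each
fold the non-test samples are split 5:3 into training and validation,
giving the overall ≈ 5:3:2 train/validation/test ratio; the sub-model
with the best validation loss is kept. Class imbalance is handled by
inverse-frequency class weights in the loss.

A new sample's per-representative probability is the mean of the five
fold models' outputs. The **ensemble** takes, within each fold, the
median of the three representatives' probabilities, then averages the
medians across folds. Taking the median of the three fold-averaged
finals instead is almost equivalent but not identical (the two orders
can differ when fold outputs straddle each other); the per-fold-first
order is implemented consistently, and the held-out ensemble used for
AUC is computed the same way. Calls are positive at probability ≥ 0.5
(boundary inclusive, as for the score cutoffs below).

## Count-based baselines

Per-bin counts on retained bins are corrected by a LOWESS fit of count
on GC percent (span 0.3, normalised to mean 1 and divided out) and by
mappability/100, then summed per chromosome. The Z-score standardises
the chromosome's genome-wide fraction against the euploid reference
cohort's mean and unbiased SD; the NCV does the same for the ratio of
the target count to its denominator set (chr9 for chr21, chr8 for
chr18, the chr2+chr3+chr4+chr5+chr6 sum for chr13). Both call positive
at score ≥ 3. Correction precedes scoring. A reference cohort of
identical samples (SD 0) or of size < 2 raises a degenerate-reference
error. Both scores are invariant to rescaling all counts, and
reference samples scored against their own statistics have mean 0 and
SD 1 by construction.

## Metrics

Sensitivity, specificity, PPV and NPV are reported in percent with two
decimals (half-up rounding) and a 95 % Wald interval
p ± 1.96·√(p(1−p)/n), n being the metric's own denominator, capped to
[0, 100]. Wald with capping — not Wilson or Clopper–Pearson — is the
convention matched here; it reproduces published NIPT benchmark tables
cell for cell, including bounds printed as 100. "Overall" positivity
pools the three trisomies: a sample called positive for any target
counts once.

## The simulator

Per bin, expected fragment intensity is
`bin width × dosage × GC-bias(GC) × mappability/100`, zero on masked
bins. Dosage is 1 + *f*/2 on a trisomic chromosome and
1 + overlap-fraction·(copy_ratio − 1) on bins covered by a maternal
CNV. The per-bin count vector is one multinomial draw of the total
yield — not independent Poissons — so per-sample depth is exact,
mirroring a fixed sequencing yield. Fragments are placed uniformly
within their bin with Bernoulli(0.5) strand; the simulator draws the
harmonised cut coordinate and derives the recorded leftmost position by
strand, with margins that keep each read wholly inside its bin (so no
fragment ever touches a masked interval). The default GC bias is a
quadratic in (GC−40)/10 with coefficients (1, 0.06, −0.04), renormalised
to mean 1 over retained bins — a mild smooth confounder that exercises
both the GC filter and the LOWESS correction. Optional duplicate and
low-MAPQ injection exists solely to exercise the input filters.

Reproducibility: a sample is fully determined by its seed; cohorts
derive per-sample seeds as (master, index) so partial or parallel
regeneration is stable.

What the simulator does *not* model: fragment-length distributions
(single-end, fixed 75 bp), sequence-level errors, per-sample GC-bias
variation, position-level chromatin structure, sex-chromosome
aneuploidy, twin pregnancies, or mosaicism. Passing tests therefore
show that the pipeline recovers the dosage signal it is designed for
under realistic depth noise and smooth bias — not that clinical
performance on real cfDNA is guaranteed.

## Desk-scale study conditions

The built-in study (`aidnipt.study.run_study`) uses:

* **Genome**: GRCh37 chromosome proportions at half scale (~1.4 Gb,
  1507 bins, 1195 retained; fixed synthetic GC/mappability tracks and
  centromere/telomere masks).
* **Depth**: 800,000 fragments per sample for image-based analyses —
  per-bin FD medians then have ~5 % relative noise against a 4–7 %
  trisomy signal, and the maternal-CNV scenario below moves the chr18
  fraction by ~5 reference SDs. The Z-power study uses 750,000
  fragments, chosen by a power calculation: the chr21 share rises by
  p·f/2 under trisomy while its SD scales as 1/√depth, giving a mean
  z of ≈ 4.7 at f = 0.10 and > 90 % detection at cutoff 3. (The
  emulated assay yields ~12 M reads; these are its desk-scale
  equivalents.)
* **Cohorts**: 150 euploid + 150 trisomy-21 samples for the chr21
  model (the euploid half doubles as the ICC/reference cohort), 150 +
  50 for the chr18 model; affected fetal fractions uniform on
  [0.08, 0.15].
* **Maternal-CNV scenario**: 30 euploid replicates carrying a 2-Mb
  one-copy duplication (copy ratio 1.5) spanning two retained chr18
  bins — the half-scale analogue of a multi-Mb clinical event. It
  pushes the count-based Z-score over its cutoff, while the affected
  bins fall strictly inside the 10 % lower-tail trim capacity (2 of a
  3-bin budget on chr18's 30 retained bins) so the TRS ensemble stays
  negative. The footprint is deliberately kept below the trim budget:
  when an event consumes the whole budget, the chromosome's own low
  tail survives untrimmed and mimics a weak trisomy shift — at half
  scale the trim budget (3 bins) is tight, whereas at full genome
  scale the same 10 % rule affords ~6–7 bins.

## Numerical choices and degenerate inputs

* Quantiles (bin median/IQR, global median) use linear interpolation
  between order statistics, numpy's default, fixed so golden values
  are stable.
* Zero distances (two reads shifted to one coordinate) are kept;
  deduplication happened upstream and is not repeated.
* Bins with fewer than 10 distances are flagged unusable — a guard
  against degenerate summaries at low depth (the threshold is a
  package choice, configurable via `min_fd_n`).
* A shifted position falling outside the bin grid is silently dropped
  at binning; a chromosome with < 2 positions yields an empty distance
  list, not an error.
* "Distance between adjacent fragments" is read as the distance to the
  *following* neighbour (successive differences). The alternative
  reading min(previous, next) would duplicate distances across pairs;
  the implemented reading keeps the sample size at n − 1 and satisfies
  the conservation identity Σ FD = max − min.
* A sample whose global median FD is 0 or undefined, an empty TRS
  segment, an all-zero count vector, and a zero NCV denominator each
  raise a specific error rather than propagating NaNs.

## Known limitations

* The CNN engine is deliberately minimal (no augmentation, no GPU, no
  batch normalisation); it is sized for TRS images, not a general
  vision stack.
* ICC selection assumes the reference cohort is euploid; contaminating
  trisomic samples bias the regressions.
* The euploid TC band sits near — but not exactly on — the ICC band:
  chromosome-specific GC/mappability composition gives each chromosome
  a stable baseline offset in normalised FD, which the classifier
  absorbs as part of the euploid pattern. Tests therefore check that
  the trisomy shift moves the TC band relative to its euploid baseline,
  not that the euploid offset is exactly zero.
* Performance is not stratified by fetal fraction, and mosaicism-driven
  false negatives (fetal trisomy with euploid placenta) are outside
  what any cfDNA method — simulated or clinical — can detect.
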
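# Methods

## Fragment model and conventions

A fragment is the interval of genome covered by one sequenced cfDNA
molecule, stored BED-style: 0-based half-open coordinates, MAPQ in the BED
score column. Alignment, pairing and duplicate removal are upstream of this
package; the reader performs no deduplication. Filtering keeps fragments
with MAPQ ≥ 30 (inclusive) and removes any fragment overlapping a
blacklist interval by at least 1 bp — any-overlap semantics, the same
partition `bedtools subtract` would produce, chosen because partial-overlap
thresholds would need a fraction no analysis step defines. Fragment GC is
computed from reference bases over [start, end); ambiguous bases (N) count
as non-GC so the GC fraction is always defined in [0, 1].

## GC correction

Fragments are assigned to 100 equal-width GC strata on [0, 1]; gc = 1 falls
in the top stratum (index = min(⌊gc·100⌋, 99)). The target distribution is
the element-wise median of the per-stratum counts of a non-cancer reference
panel — raw counts, not library-size-normalized first; since the weighted
total of every sample then equals the same target total, library-size
normalization emerges from the weights themselves, and pre-normalizing
would only rescale the target. Each fragment in stratum i receives weight
t_i / N_i, making weighted stratum counts equal the target exactly
(asserted to 1e−9 relative in tests). When a sample has no fragments in a
stratum with t_i > 0, that target mass cannot be assigned; it is dropped
and reported in a warning rather than redistributed, because any
redistribution rule would silently move mass across GC values. In practice
the dropped mass is a handful of fragments out of tens of thousands.

## Bins, profiles, arms

The genome is tiled per chromosome into consecutive fixed-size bins
(5 Mb production default; toy genomes use 50 kb so that a 10 Mb genome
still yields ~200 features). Terminal partial tiles are dropped — all bins
have identical length, so counts are comparable without length
normalization. Bins with mean GC < 0.3 or mean mappability < 0.9 are
excluded; mappability comes from any user-supplied bedGraph and defaults to
1.0 when no track is given (toy genomes are fully mappable by
construction).

Each fragment belongs to the bin containing its midpoint — a partition, so
nothing is double-counted at bin boundaries. Per bin, the weighted count of
short (100–150 bp) and long (151–220 bp) fragments gives ratio = short/long;
fragments outside both windows contribute to neither. The ratio vector is
standardized within the sample to mean 0 and SD 1 (ddof = 1) across bins,
which removes depth and any uniform weight scaling. A bin with zero
weighted long count makes the ratio undefined and raises an error naming
the bin; the synthetic depth defaults are chosen so this cannot occur
(≥ ~100 long fragments per bin in expectation).

Arm z-scores standardize the total weighted fragment count of each
chromosome arm by the mean and SD (ddof = 1) of the same quantity in the
reference panel. The human arm catalogue excludes the five acrocentric
p-arms (13p, 14p, 15p, 21p, 22p), leaving 39; toy genomes define arms by a
configurable centromere fraction. Arm boundaries for a real genome are
supplied as a cytoband-style table.

Copy-number segment tables are mapped to bins with a coverage rule: a bin
is a gain (loss) iff segments whose log ratio exceeds (falls below) a
cohort-specific threshold cover ≥ 90% of the bin; otherwise neutral.
Thresholds are configuration values because they are tumor-type-specific.
The rule is verified against a per-base oracle on randomized layouts.

## Classifier

Features are the standardized bin ratios (X) and arm z-scores (Z). Within
each training set, X is centered per bin by training means and decomposed
by SVD; the minimum K with cumulative explained variance ≥ 0.90 is kept.
PCs and z-scores enter an L1-penalized logistic regression unstandardized —
PCs are variance-ordered by construction and z-scores already panel-scaled.
The penalty follows the glmnet convention, (1/n)·logloss + λ‖w‖₁, mapped
to scikit-learn via C = 1/(n·λ) with the saga solver (which, unlike
liblinear, leaves the intercept unpenalized, so full shrinkage collapses
predictions to class prevalence as it should); λ defaults to 0.0017 and can
instead be chosen from a grid by stratified resampled log-loss. The same λ
is used across CV folds.

Scores are out-of-fold probabilities from stratified 5-fold CV repeated 10
times, averaged per sample; all fold draws descend from one seed and
per-fold coefficients are retained for stability reporting. If a drawn
training fold is single-class (possible only at extreme imbalance), folds
are re-drawn within the repeat and a warning logged. The score cutoff θ is
the smallest score at which the fraction of non-cancer scores ≤ θ reaches
the target specificity — the tie-break toward higher sensitivity —
and classification is strict: positive iff score > θ. External cohorts are
scored by a frozen model: training bin means for centering (the per-sample
genome-wide standardization already happened in the profile step, so
centering here is across-sample and must not be recomputed on the new
cohort), stored loadings, stored coefficients.

The multimodal variant appends age (years), smoking pack-years, COPD
status (0/1) and log(1 + CEA); CEA is log-transformed because it is
heavy-right-skewed over orders of magnitude, a choice this package makes
where the original feature description leaves the scale open.

Uncertainty: binomial sensitivities/specificities get equal-tailed Jeffreys
intervals (quantiles of Beta(k+½, n−k+½), checked against numeric
integration of the posterior density to 1e−6); AUCs get percentile
bootstrap intervals (2,000 resamples, resamples with one class discarded
and redrawn). The described model is the LASSO-logistic pipeline throughout;
no tree-based alternative is implemented.

## TFBS footprint statistics

Tissue-specific factors are ranked from a genes × samples TPM matrix: keep
factors with median TPM < 1 (strict) in every off-tissue group, sort
descending by median TPM in the target group. Peaks are restricted to
autosomes; the peak center is ⌊(start + end)/2⌋. Coverage at a position is
the number of fragments overlapping it (full-interval pileup, not midpoint
counting — overlap is the quantity nucleosome protection acts on); per
sample, coverage is averaged across peaks at each offset in ±3000 bp.
Windows that would leave the chromosome are skipped with a warning. Peaks
whose cross-sample average window coverage exceeds 3 (strictly) are
excluded as repeat-like pileup artifacts.

Relative coverage = mean coverage over offsets [−100, +100] divided by the
mean over [−3000, −2500] ∪ [+2500, +3000] (both flanks pooled). Relative
fragment size uses only fragments < 200 bp: the mean length over the center
window divided by the mean over [−1500, −1000] ∪ [+1000, +1500]. Window
means pool length-sums and counts across offsets (a ratio of sums) rather
than averaging per-offset means, which is undefined at sparsely covered
offsets and identical on dense data. Overexpression calls flag samples
with TPM > mean + 3·SD (ddof = 1) for the gene across all samples; zero
variance yields all-false.

## Screening-population model

One arm is a modality with four priors: sensitivity θ₁ (for imaging
anchored to the LUCAS cohort, a 0.5/0.5 mixture of N(0.96, 0.005) and
N(0.94, 0.02) — the spread parameters are treated as standard deviations,
since variances of that size would put most mass outside [0, 1]; draws are
clipped to [0, 1]; other arms use Beta(93.8, 6.2), Beta(85, 15),
Beta(91, 9)), specificity θ₂ (Beta(58, 42) / Beta(93.8, 6.2) /
Beta(86, 14) / Beta(94, 6)), adherence η (Beta(12, 188) imaging-only,
mean 6%; Beta(15, 11) blood-first, mean ~58%), and prevalence
ψ ~ Beta(9.1, 990.9), mean 0.91%. Per repetition: n ~ Bin(100000, η),
cancers ~ Bin(n, ψ), TP ~ Bin(cancers, θ₁), FP ~ Bin(n − cancers, 1 − θ₂) —
count-level sampling, distributionally identical to per-individual
Bernoulli draws and orders of magnitude faster. 10,000 repetitions give
predictive distributions (mean, equal-tailed 95% interval) for detections,
tested n, prevalent cases over the whole population, accuracy
(TP + TN)/n, unnecessary procedures FP and FP/n, and PPV TP/(TP + FP);
draws with an undefined ratio are excluded from that statistic and counted.
Accuracy and rates use tested individuals as the denominator. Arm
comparisons share the prevalence draws by default (one common population),
so per-draw detection ratios are paired; fold intervals come from the
percentiles of those ratios, excluding zero-denominator draws. Any prior
can be replaced by a point mass, which is how closed-form expectations are
checked in tests. PPV predictive means under these priors sit near their
plug-in values (e.g. ~12% for the NLST-anchored imaging arm), which is
what the stated priors imply; PPV is therefore reported but not treated as
a reproduction target.

## Synthetic data generator

The generator emulates the features the pipeline measures, on a toy genome
(default 2 chromosomes, a smooth GC landscape varying ~0.35–0.55, uniform
mappability, arms split at a configurable centromere fraction):

- fragment sizes: truncated normals on [50, 400] bp — non-tumor mean 167,
  SD 10 (the nucleosome + linker mode of plasma cfDNA); tumor mean 145,
  SD 15, reflecting the shorter, more variable tumor fragmentation the
  method exploits. Exact published size densities are only available
  graphically, so these are configurable defaults.
- tumor-fraction mixture: each fragment is tumor-derived with probability
  tf; tumor fragment positions are weighted by the local copy ratio of
  configured CNA segments (1 kb position resolution), so expected bin
  occupancy is proportional to (1 − tf) + tf · copy_ratio.
- GC amplification bias: candidates are accepted with probability
  ∝ exp(β·gc), the multiplicative PCR-style bias the stratum reweighting
  is designed to remove.
- TFBS footprints: tumor fragments overlapping site-center ± 100 bp are
  thinned by the depletion factor. Because only tumor fragments are
  thinned, the observed relative-coverage depletion equals tf × depletion;
  footprint-recovery tests use tf = 1 so the injected and measured
  depletion coincide.

All randomness descends from one seed per sample/cohort; identical seeds
reproduce byte-identical fragment tables. Controls are tf = 0. Optional
clinical covariates are drawn with class-conditional shifts (older, heavier
smoking, more COPD, lognormally higher CEA in cases).

What the generator does *not* emulate: real chromatin structure (no
nucleosome phasing beyond the size distribution), mappability holes,
subclonal copy-number heterogeneity, focal amplifications, sequencing
error, or between-individual biological variability in the fragmentation
background. Passing tests therefore demonstrate the pipeline's correctness
and its recovery of injected effects, not clinical performance on real
plasma.

## Problem sizes and numerical choices

The test and reproduction workloads use a 2 × 5 Mb toy genome with 50 kb
bins (200 bins), reference panels of 6–20 samples, cohorts of 40 + 40
samples at 50,000 fragments each, and 10,000 Monte Carlo repetitions for
the screening model — sizes chosen so the full suite runs on a laptop-class
single core in minutes while leaving every statistical check well-powered.
Monte Carlo reproduction tests compare means within 3 Monte Carlo standard
errors plus half a unit of the printed value's precision (published values
are rounded integers); quantiles use a bootstrap SE. The null-calibration
check of the cross-validated AUC averages 3 seeds because a single 40 + 40
cohort has an AUC sampling SD (~0.065) comparable to the acceptance band.
Standardization SDs use ddof = 1 throughout. Ties in cutoff selection break
toward higher sensitivity; classification is strictly greater-than.

## Known limitations

- The production hg19 bin list (the 473-bin tiling) depends on the identity
  of the mappability track and blacklist; the package computes bins from
  whatever tracks are supplied rather than shipping a fixed human fixture.
- Weights for strata unobserved in a sample drop target mass (warned, not
  redistributed); extremely shallow samples with many empty strata will
  lose more.
- PPV predictive summaries follow directly from the stated priors; they
  are not calibrated to any external PPV estimate.
- The multimodal covariate model is additive on the logit scale; no
  interactions.
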
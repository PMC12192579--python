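# Methods

This note documents the statistical model behind `mlgscan`, the
numerical choices made where the design was genuinely open, what the
synthetic-data generator does and does not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

The scan treats a genome as a long sequence of overlapping observation
units ("stretches") and asks which units are outliers relative to the
empirical distribution of all units. No generative model of the
underlying evolutionary process is assumed; the only assumptions are
that (i) most of the genome is "typical", so the bulk of the feature
distribution defines normality, and (ii) unphased biallelic genotypes
coded as alternate-allele counts {0, 1, 2} carry enough signal in their
window-level MLG diversity to distinguish atypical regions.

### Window statistics

Within an ℓ-SNP window, the m = 8 statistics are the population (biased,
divide-by-count) mean, variance, skewness m₃/m₂^1.5 and excess kurtosis
m₄/m₂² − 3 of the n(n−1)/2 pairwise scaled Manhattan distances, plus the
four top MLG frequencies. Conventions fixed here: zero-variance inputs
return skewness = kurtosis = 0 (rather than NaN) so downstream matrices
stay finite, with a relative noise floor of 1e-28 on the variance to
absorb float rounding on constant vectors. Distances live in [0, 2] and
are invariant to REF/ALT re-polarization; all statistics are invariant
to permuting individuals.

### FDA features

Each statistic's curve across a w-window stretch is fit by ordinary
least squares on B clamped cubic B-splines with equally spaced interior
knots on [1, w] (B − 4 interior knots). There is no roughness penalty:
with w = 129 samples and B = 10 basis functions the fit is already
heavily smoothed by the basis dimension, and plain least squares keeps
the features an exact linear function of the data (useful for testing
and reasoning; cubic polynomials are reproduced to machine precision).
Derivatives are evaluated analytically from the basis derivative
matrices and re-projected onto the same B-dimensional basis by least
squares, so each derivative contributes exactly B features per
statistic. Feature ordering is fixed (statistic-major; fit block, then
first- and second-derivative blocks) for reproducibility.

A structural consequence, discovered during implementation and worth
stating plainly: because the derivative features are exact linear images
of the fit coefficients (D1 = PΦ′c with P the fitting operator), the
nominal 3Bm = 240-column FDA matrix has rank at most Bm = 80. The
derivative blocks change the *geometry* (and hence IF/SVM behaviour and
any weighted treatment of features) but add no dimensions to the column
space, and the FDA covariance matrix is always singular. Similarly, in
windows where all n MLGs are distinct — the typical neutral case — the
MLG-frequency statistics are constant at 1/n, making entire moment
columns constant.

### Mahalanobis scoring with degenerate covariances

Because of the rank deficiencies above, the pipeline's Mahalanobis route
uses the Moore–Penrose pseudoinverse of the sample covariance: distances
are computed within the data's support subspace (singular values above
1e-8 of the largest retained), and the *effective rank* r — not the
nominal column count — is used as the numerator degrees of freedom in
the Hotelling-to-F transform F = D²(N − r)/(r(N − 1)). When the
covariance has full rank this coincides exactly with the classical
definition, and the trace identity Σᵢ D²ᵢ = r(N − 1) holds either way. A
strict plain-inverse variant (error on singularity, optional ridge
regularization) is kept for callers with well-conditioned features.

### p-value calibration

Raw p-values from the F transform are mis-calibrated in two ways on real
(and realistic synthetic) genomes: overlapping stretches are strongly
autocorrelated, and moment features of skewness/kurtosis are
heavy-tailed, so the F tail is too light. Calibration is genomic-control
style on the χ²(1 dof) quantile scale, with λ the through-origin slope
of observed on expected quantiles at plotting positions (i − 0.5)/N
(p-values of exactly 1 clamped to 1 − 1/(2N); p-values of exactly 0 are
an error in the estimator, so the pipeline floors raw p at 1e-300, below
any representable nonzero tail probability).

Two slope estimators are provided. The least-squares slope is dominated
by the largest quantiles — it matches the extreme tail, which is what
determines calls, but is dragged far upward when genuine anomalies
occupy a visible share of the tail (at desk scale a 400-SNP planted
region contaminates ~10% of stretches and pushed λ to ~56, erasing all
power). The L1 slope (exact minimizer of Σ|q_obs − λ·q_exp|, a weighted
median of quantile ratios) tracks the null bulk and ignores the signal,
but under-corrects heavy tails. The pipeline therefore iterates: start
from the L1 slope, call provisional outliers at α, refit the
least-squares slope on the non-called remainder, repeat to a fixed
point. λ is clamped at 1 throughout: apparent deflation (λ < 1, which
arises when planted signal swells the covariance and shrinks null
distances) is never used to *inflate* significance, following standard
genomic-control practice. Measured across simulation seeds 1–5 by the
test suite's scenario: neutral genomes yield 0–6 calls out of 5822
stretches and planted regions are recovered with zero calls outside the
affected footprint.

One honest caveat the tests encode: on neutral LD-structured genomes the
single-shot regression λ for the moment-feature Mahalanobis route is
~1.6–2.0, not ~1 — moment features are genuinely heavy-tailed, and that
inflation is exactly what the correction absorbs. The FDA route is
nearly calibrated from the start (λ ≈ 0.86–1.07), consistent with
spline fits modelling away the LD-induced autocovariation; the test
suite asserts the ~1 band only for the FDA route.

### Detector conventions

IF and SVM follow the scikit-learn conventions: decision values with
lower = more anomalous; IF uses 100 trees and subsample 256 with a
mandatory seed; the one-class SVM uses an RBF kernel, gamma = "auto",
ν = 0.5, trained per mini-batch of a systematic-sampling plan (row r →
batch r mod m, m = 18) and scoring each row with its own batch's model
(a flag switches to mean-over-batches scoring). Their scores enter the
p-value machinery as a single feature: shift-log transform
s′ = log(s − min s + ε), ε = 10⁻⁶ · range(s), then the squared
standardized score referred to F(1, N − 1). The transform is strictly
monotone, so detector rankings are preserved.

## Synthetic data

The generator draws per-site alternate-allele frequencies uniformly on
[0.05, 0.95] and builds two pseudo-haplotypes per individual
left-to-right: with probability ρ a site copies its left neighbour's
allele on the same haplotype, otherwise it draws Bernoulli(f). Defaults
(n = 60, L = 6000, ρ = 0.5, mean SNP spacing 500 bp) are the package's
desk-scale stand-in for a sequenced population sample: ρ = 0.5 produces
neighbour correlations strong enough to exercise the FDA features, and
the frequency band avoids near-monomorphic sites a caller would filter.
What it does **not** emulate: coalescent genealogy, recombination-rate
variation, demography, allele-frequency spectra under drift/selection,
genotyping error, or missing data. A green pipeline test therefore
establishes that the machinery is self-consistent and has power against
large planted signals in an LD-structured null — not that the method's
error rates transfer to real cohorts.

Injected anomalies are deliberately large so power checks are robust at
desk scale: excess heterozygosity (P(het) = 0.9, a caricature of
balancing selection), MLG-spectrum collapse to two strings at 0.5/0.5
(strong haplotype structure), and a dropout artifact (30% of individuals
forced homozygous reference, a genotyping-failure caricature).

## Other numerical choices

- Coordinates are 0-based half-open (BED) everywhere; VCF positions are
  converted on load and restored on write.
- Sites with any missing genotype call are dropped on load (keeps every
  window a complete {0,1,2} matrix); the count is logged.
- ℓ and w must be odd so windows and stretches have a unique center SNP
  / window, which anchors all genomic bookkeeping.
- The exact multinomial test enumerates all outcome compositions when
  the total count is ≤ 500 and the outcome space is ≤ 5·10⁵, summing
  probabilities ≤ that of the observed table (with a 1 + 1e-12 relative
  guard against float ties); otherwise it falls back to the χ²
  goodness-of-fit approximation and says so in its return value.
- The two-tailed binomial test is the minimum-likelihood convention (it
  reduces to doubling one tail at p = 0.5).
- Genic sub-label precedence when annotation intervals overlap:
  5′UTR/3′UTR > exon > intron; "longest transcript" is the maximal
  end − start per gene symbol, ties to the first in file order; a genic
  anchor hitting no feature interval defaults to intron.
- Peaks are maximal runs of consecutively significant stretches within a
  chromosome (adjacent rows in anchor order) — the notion is not given a
  formal definition elsewhere, so this one is ours.
- Anchors label a whole stretch by its center position only, including
  for annotation intersection; a stretch spanning multiple annotation
  classes contributes only where its anchor falls.

## Limitations

- The six methods share one feature pipeline: errors there propagate to
  all of them.
- λ is estimated genome-wide per method, not per chromosome.
- The pseudo-inverse rank cutoff (1e-8 relative) is a hard threshold; a
  feature direction with genuine but tiny variance near the cutoff would
  be silently dropped.
- Power against *subtle* anomalies (weak selection, mild batch effects)
  at desk scale is untested by design; the planted signals are coarse.
- Sex chromosomes, multi-allelic sites, phased information and
  imputation are out of scope; sites with missing calls are discarded
  rather than imputed.
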
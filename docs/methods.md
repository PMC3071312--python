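# Statistical methods and design notes

This document records the models behind each estimator, the rationale for
default parameters, and the validation studies that back them.  All
validation is against synthetic data with planted ground truth
(`evotol.synth`), summarized by the studies in `evotol.validation`.

## Growth-rate estimation (`evotol.growth`)

**Model.** The maximum specific growth rate mu_max (h^-1) is the slope of
an ordinary least-squares regression of ln(OD600) versus time over the
exponential phase, after subtracting a plate-level blank (median OD of the
designated blank wells over all time points).

**Window selection.** The exponential phase is located automatically:
every contiguous window of at least `min_points = 6` blank-corrected
points above the positivity floor is scanned.  A window qualifies when its
regression has R^2 >= 0.98 and its fitted ln-range (slope x time span)
covers at least one natural-log unit (~1.44 doublings), which rejects
short windows that only track noise.  Among qualifying windows the
selected one maximizes a lower-confidence-bound score

    slope − z * SE_model,      z = 4 by default,

where SE_model is the slope standard error predicted from a
heteroscedastic noise model: additive OD noise of magnitude sigma implies
ln-scale noise ~ sigma / OD, so early low-OD points are penalized.
Ranking windows by raw slope instead (the classical rule,
`selection="slope"`) is upward-biased under noise because the maximum over
many windows selects positive noise excursions; the LCB score removes
most of that bias.  sigma is either supplied (`noise_sd`) or estimated
from successive differences of the final 31 readings.  Ties go to the
longer, then earlier, window.  The positivity floor is
`max(floor, 3 * sigma)`.

**Calibration.** On synthetic plates (289 points/well over 48 h at
10-minute intervals, three-phase curves, additive noise SD 0.002 OD,
planted mu in 0.2–0.8 h^-1) the mean absolute error is ~0.6% of the
planted rate over 100 wells (criterion: < 2%), and the selected window
matches an independently implemented exhaustive-search oracle on every
well (`validation.growth_recovery_study`, `growth_window_oracle`).

## Epistasis (`evotol.epistasis`)

**Model.** Under the multiplicative null the relative fitness of a
combination equals the product of its singles; total epistasis is
epsilon_S = w_S / prod w_i, reported as log10(epsilon).  Significance
comes from a CI for log10(epsilon): delta method on the log scale
(variance = sum (SE_i/w_i)^2 / ln(10)^2 + (SE_w/w)^2 / ln(10)^2), normal
or Student-t quantile, or a seeded percentile bootstrap over replicate
means when replicate-level values exist.

**Calibration.** On 1000 multiplicative-null K=5 landscapes with
lognormal noise (log-SD 0.05, analytic delta-method SEs), the 95%-CI
false-positive rate is ~5.5% (criterion: <= 7.5%).  On noiseless planted
landscapes the recovered epsilon is exact to machine precision.

## Mutation catalogs and variant triage (`evotol.genotype`)

Catalog coordinates are 1-based; coverage intervals are 0-based half-open
(converters provided).  Triage keeps SNPs with consensus quality >= 150
and indels with supporting-read frequency >= 0.4 (boundary values kept);
a stricter quality > 200 preset is provided for Sanger-verification
candidate lists.  Candidate large deletions are maximal runs of
zero-coverage intervals of total length >= 1 kb.  The homopolymer filter
discards reads containing a single-base run strictly longer than 10.
All three are verified exactly against planted candidates, a planted
9,900 bp gap, and a regex oracle.

## Microarray pipeline (`evotol.expression`)

The cascade is: per-spot background subtraction (negatives retained);
technical-replicate medians per probe and array with an acceptance rule
(a probe must be acceptable in >= 2 of 3 biological replicates per
condition or its values there are set missing); variance-stabilizing
generalized-log transform glog(x) = asinh(x/lam)/ln 2 (lam from a robust
scale of the nonpositive values when not supplied); unweighted quantile
normalization (postcondition: identical sorted columns for tie-free
input); one probe per gene by minimum summed replicate SD; an intensity +
IQR gene filter.

**Moderated t.** Per gene, within-group variances are pooled and shrunk
toward a prior s0^2 with d0 prior degrees of freedom, both fitted to the
ensemble of gene variances by a method-of-moments match of the log-variance
distribution (trigamma inversion); the moderated t uses the shrunk
variance with df + d0 degrees of freedom.  `prior_df=0` recovers the
ordinary Student t exactly (verified to 1e-10).  BH step-up adjustment
controls FDR; on complete-null simulations (200 runs x 2000 genes) the
empirical FDR at q = 0.05 is ~0.05 (criterion: <= 0.075).

Dataset-level gene counts from any specific experiment depend on the
exact commercial-array normalization used there and are out of scope; the
cascade is instead validated against brute-force oracles and planted
truth on synthetic data.

## Network component analysis (`evotol.nca`)

**Model.** E ~ A @ P with support(A) fixed by a binary connectivity Z.
Identifiability requires (i) generic full column rank of A on its
support, (ii) full column rank of each TF-deleted reduced matrix, and
(iii) at least as many samples as TFs; `check_identifiability` tests all
three on a random filling of the support.

**Decomposition.** Alternating least squares with per-support-pattern
batched A-steps.  Random initializations stall in local minima roughly
half the time; initializing A to ones on the support empirically reaches
the global optimum on identifiable noiseless problems, so that start is
always run first, followed by seeded random restarts (best final residual
wins).  Exit convention: unit-norm loading columns with the majority of
loadings positive (majority sign is stable across gene subsets; the
single largest loading is not).  Noiseless recovery: per-TF
|activity correlation| = 1 to 1e-3 tolerance on 200-gene x 4-TF x
4-condition instances; >= 0.95 at 10% noise.

**Subset consensus.** With c conditions, one decomposition can resolve at
most c TFs — and only c−1 after per-gene row-centering (which removes
gene baselines exactly but costs one rank).  For panels larger than that,
`subset_consensus` decomposes many small TF subsets and retains a TF only
when three conditions hold:

1. **Sign consistency** >= 0.8 of its subset-level contrasts share the
   majority sign.
2. **Permutation test** (per TF, level 0.05): the median subset-level
   |contrast| against a null that shuffles condition labels once per
   biological replicate per iteration, applying the same shuffle to every
   subset's activities from that replicate.  Subsets reuse the same
   replicate data, so they are not independent evidence; replicates are
   the exchangeable units.  The permutation group is small (with r
   replicates of c conditions, (c!)^r shuffles), so Bonferroni-corrected
   permutation levels are unreachable; family-wise control is delegated
   to the third condition.
3. **Replicate t-test** (family-wise level 0.01, Bonferroni over the TF
   panel, r−1 degrees of freedom): the per-replicate mean contrast must
   differ from zero.  True activity changes recur in every replicate and
   give very large t values; chance alignments do not.

Per decomposition, each TF's statistic is its activity-contrast scaled by
the root-mean-square of its loadings on its *anchor genes* (genes it
regulates alone in the full network).  This product is invariant to the
per-TF scale/sign indeterminacy and collapses to ~0 for a
constant-activity TF that merely absorbs a co-regulated changing TF's
pattern (such leak solutions put near-zero loadings on the anchors).
Signs are aligned across subsets via the anchor-gene loadings.  Genes
with any regulator outside the subset are excluded, because their
expression violates the subset model.

**Calibration.** On 16-TF, 4-condition, 3-replicate instances with 4
planted changing TFs at low noise, the procedure retains exactly the
planted set in >= 90% of seeded runs and retains nothing on null data in
>= 95% of runs (`validation.consensus_study`).

## qPCR (`evotol.qpcr`)

MAK2 models amplification by F_n = F_{n−1} + k ln(1 + F_{n−1}/k) with
F_0 = D0: perfect doubling while F << k, saturating as F grows.  Fitting
the recurrence to the pre-plateau window (cycles up to the first reading
above 85% of the curve maximum) by multistart nonlinear least squares
yields D0 without standard curves; relative expression is
D0_target / D0_reference.  Noiseless recovery is exact to ~1e-15 relative
error; the one-cycle value F_1 = 1 + ln 2 for (D0 = 1, k = 1) is checked
to 1e-12; doubling D0 at fixed k is recovered as a 2x ratio within 5% at
1% noise.

## Synthetic data (`evotol.synth`)

All generators are pure functions of their parameters and an integer
seed; per-generator substreams are derived by hashing a fixed string
label into the seed sequence, so adding one generator never perturbs
another's draws.  Growth curves are three-phase (flat lag, exact
exponential, C1-continuous logistic saturation) so the planted in-window
slope is exact.  Expression datasets are generated as loadings x planted
activities through a sparse connectivity whose per-gene regulator counts
follow a truncated geometric law (mean 1.5 regulators/gene), matching the
sparsity regime NCA assumes.

## Problem sizes and runtime

The full test suite, including the 50 + 50 consensus runs, completes in
roughly 10–12 minutes on one CPU; `scripts/acceptance.py` is comparable.
The heaviest single component is the subset-consensus study (~5 s per
instance: 60 TF-subsets x 3 replicate decompositions plus a shared
499-iteration permutation null).
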
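# Methods

## Overview

`ilc2kit` implements the computational workflow of a knockout-vs-wildtype
bulk RNA-seq study design together with its downstream molecular and
bench-side analyses: differential expression by a batch-stratified
hierarchical negative-binomial model, gene-set overrepresentation and
score-based enrichment, canonical miRNA seed-site scanning with
nearest-neighbor duplex free-energy scoring, and the quantification
procedures used at the bench (2^-ΔΔCt relative qPCR quantification,
two-channel reporter knockdown normalization, within-host chimera MFI
normalization, and a normality-gated two-sample test dispatch).  All
pipeline inputs can be generated by the synthetic-data module with
known ground truth, which is how the package validates itself.

## Count model

For gene *g*, sample *j* with batch *b(j)* and knockout indicator
*x_j*:

    y_gj ~ NB(mu_gj, alpha_g),           Var = mu + alpha mu^2
    log mu_gj = log s_j + a_{g,b(j)} + beta_{g,b(j)} x_j

* `s_j` — size factors, computed by median-of-ratios **within each
  batch** and constrained to geometric mean 1 per batch.  They enter
  the model as fixed offsets; between-batch depth differences are
  deliberately left to the batch intercepts.  An upper-quartile
  variant is available; a batch with no all-positive reference gene
  falls back to total-count ratios with a warning.
* `a_gb` — per-batch varying intercepts, partially pooled:
  `a_gb ~ Normal(m_g + d_b, sigma_g)` with `sigma_g ~
  HalfNormal(prior_sd_intercept_pop = 1)`.  The pooling center is a
  free gene-level parameter `m_g` (weak prior
  `Normal(log mean normalized count, prior_sd_center = 2)`) plus a
  global batch offset `d_b`, a fixed constant computed as the median
  across genes of the batch deviation of log means.  Two structural
  details matter.  The batch offset: pooling both intercepts toward a
  batch-blind center biases them whenever a genuine batch shift
  exists, and because intercepts are informed by WT samples while KO
  samples inform intercept+effect, the bias leaks with opposite sign
  into the effect coefficients.  The free center: pinning `m_g` to an
  empirical value lets the `sigma -> 0` limit clamp the intercepts to
  data-derived numbers, which double-uses the data (overconfident
  intervals) and, when the empirical center includes KO samples,
  creates a spurious posterior mode in which the effect absorbs only
  part of a true genotype difference.  With `m_g` free, `sigma -> 0`
  degenerates to a shared offset intercept across batches — a
  legitimate submodel with correctly propagated uncertainty.
* `beta_gb ~ Normal(0, prior_sd_effect = 1)` — batch-specific KO−WT
  coefficients on the natural-log scale.  The reported quantity is
  the simple across-batch average `beta_avg_g = mean_b beta_gb`.
* `alpha_g ~ HalfNormal(dispersion_prior_sd = 1)` — gene-wise NB
  dispersion.

Genes are modeled independently (no shrinkage of effects across
genes).  The low-count filter (drop genes with across-sample mean
< 3; the boundary mean = 3 is kept) is applied to raw counts before
normalization; the order is configurable.

### Inference

Two routes share the same posterior density:

* `map_laplace` (default): L-BFGS maximization with analytic
  gradients over `[m, a_1..a_B, beta_1..beta_B, log sigma, log alpha]`
  (Jacobian terms included, so the mode is taken on the transformed
  scale), followed by a Gaussian (Laplace) approximation from a
  central-finite-difference Hessian.  Credible intervals and sign
  probabilities use Student-t quantiles with residual-style degrees
  of freedom (n_samples − 2B − 1) rather than normal quantiles: the
  Gaussian-at-the-mode approximation understates the posterior spread
  by roughly 10% at n = 4–6 per cell (heavier-than-normal tails from
  dispersion and pooling-scale uncertainty), and the t quantile
  restores near-nominal coverage (≈95% measured) and a ~5% null
  false-call rate under the 95%-CI rule.  Hessian eigenvalues are floored
  at 1e-2 before inversion because a mode pinned at a transform
  boundary (sigma → 0 when batch intercepts coincide) leaves a flat
  or slightly negative curvature direction; the floor caps the
  directional posterior sd at 10.  Retained "draws" are samples from
  the Gaussian approximation, with the log-scale coordinates clipped
  to the optimizer's box.
* `mcmc`: an affine-invariant ensemble sampler (emcee) initialized
  from a Laplace-scaled cloud around the MAP.  Walkers of an ensemble
  are coupled and individually short, so convergence is monitored by
  an R-hat computed across walker *groups* (4 groups, flattened
  within group); fits with grouped R-hat > 1.05 are flagged, not
  silently accepted.  The integrated autocorrelation time of this
  posterior is roughly 25-50 steps, hence a minimum of 600 retained
  steps per walker.  The grouped R-hat is itself noisy at these chain
  lengths and flags conservatively.

Both routes are deterministic given the config seed.  On simulated
data the two agree on posterior-mean average effects to within about
0.1 natural-log units for well-expressed genes; residual differences
are posterior skewness (mode vs mean) plus Monte-Carlo error.

### DE calling and checking

The default call declares a gene over/under-expressed when the 95%
credible interval on `beta_avg` excludes zero; a posterior-sign
probability rule (`P(beta_avg > 0) >= threshold`) is available.  On
null simulations the CI rule's false-call fraction is ~3%, i.e.
slightly conservative at the nominal 5%.

Posterior predictive checks simulate replicate datasets from retained
draws and locate the observed per-gene mean, variance and zero
fraction within the predictive distribution (mid-quantile convention:
ties contribute half, so a typical observation sits near 0.5).

## Enrichment

* Overrepresentation: one-sided upper-tail hypergeometric test of a
  DE gene list against each gene set, `P(X >= k)` with
  `X ~ Hypergeom(N, m, n)`; set members are intersected with the
  universe (genes surviving the low-count filter) before testing.
* Score-based enrichment: a Welch two-sample t comparing set members'
  per-gene scores (e.g. posterior-mean average effects) against all
  non-members, with Welch–Satterthwaite degrees of freedom and
  one- or two-sided p-values.  This is a deliberately simplified,
  score-level variant of generally-applicable gene-set enrichment,
  not a clone of the published tool's pairwise-sample design.
* Benjamini–Hochberg adjustment across sets, per method.

## miRNA target analysis

Seed sites follow the canonical taxonomy: the 6mer core is the
Watson–Crick reverse complement of miRNA positions 2–7; a match to
position 8 on the 5' flank (as read on the UTR) gives 7mer-m8, an A
opposite position 1 on the 3' flank gives 7mer-A1, both give 8mer.
G·U wobbles are not accepted in the seed match.  UTR coordinates are
0-based half-open; miRNA positions in prose are 1-based 5'→3'.

Duplex stability is scored by a dynamic program over intermolecular
base pairing only (no intramolecular structure): chains of pairs,
strictly increasing on the miRNA and strictly decreasing on the
target, joined by nearest-neighbor stacks, bulges or internal loops
(≤ `max_loop` = 15 unpaired bases per strand; internal-loop asymmetry
penalized at 0.6 kcal/mol per unpaired-base difference, capped at
3.0).  Energies come from a versioned JSON table shipped as package
data (`turner2004-like-1.0`): Watson–Crick/Watson–Crick stacks use
the standard Turner 2004 values; wobble-containing stacks are
approximate; loop initiations use Jacobson–Stockmayer extrapolation
beyond the tabulated sizes; the duplex-initiation term is zero,
matching hybridization tools that score intermolecular stacking only,
and terminal A-U/G-U pairs pay +0.45 kcal/mol per helix end.  The
empty duplex scores 0, so the reported MFE is never positive.  Ties
are broken toward fewer pairs, then the smallest miRNA start index.
The DP is verified against exhaustive enumeration of all legal
pairings on short sequences.  Because the energy table is not an
exact copy of any published tool's parameter set, absolute MFE values
for specific literature interactions are expected to deviate from
published figures; comparisons within this package (wild-type vs
mutated site, perfect vs mismatched duplex) are the supported use.

Seed mutagenesis substitutes up to 3 bases in the middle of the seed
core, avoiding bases that could still pair (including wobble) with
the opposing miRNA base, and verifies by re-scan that no canonical
class remains at the interval.

## Quantification procedures

* 2^-ΔΔCt: replicate Ct values are averaged per (condition, gene)
  first (classic Livak formulation); ΔCt = Ct_target − Ct_reference
  within condition; ΔΔCt = ΔCt_treated − ΔCt_control;
  fold = 2^−ΔΔCt.
* Reporter knockdown: per well, readout MFI (NGFR) divided by
  transfection-control MFI (Thy1.1); replicate ratios averaged per
  vector; the miRNA-vector average divided by the empty-vector
  average, which is thereby set to 1.  The order — ratio per well,
  then average — is part of the definition.
* Chimera normalization: marker MFI of the test population divided by
  the congenic reference population within the same host; hosts
  missing a population are skipped with a warning.
* Test dispatch: Shapiro–Wilk on each group; Welch t (two-tailed)
  when both groups pass at alpha = 0.05 (AND logic), Mann–Whitney U
  (two-sided) otherwise.  Zero variance in both groups forces the
  Mann–Whitney route (Welch undefined).  The exact U distribution is
  used for tie-free samples with both n ≤ 8, the tie-corrected normal
  approximation otherwise.

## Synthetic data: what it emulates and what it does not

`simulate_counts` emulates a two-batch, two-genotype bulk RNA-seq
design: NB counts with gene-wise log-normal dispersions (median
scale 0.1, log-sd 0.3, mean-corrected), log-uniform base means over
(100, 10000) — about 1e6 counted reads per sample at the default 500
genes, a typical bulk depth scaled to the simulated gene count —
batch intercept shifts of ±0.3 on the log scale, log-normal size
factors (sd 0.2, renormalized to geometric mean 1 per batch), and a
sparse set of true effects (half up, half down) of magnitude log 2.
Defaults of 4 samples per genotype×batch cell reflect the small
cohort sizes typical of such studies.

The generator matches the fitted model's family, so parameter
recovery and calibration results demonstrate correctness of the
implementation, not robustness to model misspecification: real data
have correlated genes, composition effects, outlier samples and
dispersion-mean trends that are not simulated.  `simulate_utr`
implants clean canonical sites in a uniform-composition background
with accidental seed cores rejection-sampled away and flanking bases
constrained so an implant's class cannot be upgraded — real UTRs
have biased composition and overlapping regulatory context.  Ct and
MFI simulators add i.i.d. Gaussian (cycles) or log-normal
(fluorescence) noise.

All simulators are pure functions of (config, seed).

## Numerical choices

* NB parameterization fixed package-wide: Var = mu + alpha mu^2
  (alpha = 1/size).
* Optimizer box: intercepts in [−30, 30], effects in [−15, 15],
  log sigma in [−8, 4], log alpha in [−12, 5].
* Energy comparisons in the DP use a 1e-9 tolerance for tie-breaking.
* Degenerate inputs: all-zero genes are rejected (filter first);
  batches need ≥ 2 samples and both genotypes; Shapiro–Wilk on a
  constant group is treated as a normality failure.

## Known limitations

* At the default study design (2 batches, 4 samples per
  genotype×batch, dispersion ~0.1), the sampling noise of any
  near-unbiased per-gene effect estimator has sd ≈ 0.16 on the
  natural-log scale (≈ sqrt(0.25·alpha)); with 20% of genes at
  |lfc| = log 2 this caps the attainable Pearson correlation between
  estimates and truth at about 0.89 regardless of estimator — more
  samples or lower dispersion, not a better fit, is what moves it.
* Grouped R-hat over coupled ensemble walkers over-flags at the
  default chain lengths; flagged fits are usually usable (the flag is
  deliberately conservative).
* The energy table is versioned package data, not a reproduction of
  any published tool's parameters; absolute kcal/mol values are
  approximate.
* The score-level enrichment variant ignores the sample-level
  resampling of the published gene-set enrichment design.
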
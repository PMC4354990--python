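# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic cohorts do and do not
emulate, and the numerical decisions a maintainer would want to know.

## The design

Each patient contributes a matched trio — normal kidney (NK),
nephrogenic rest (NR) and Wilms tumour (WT) — so every two-tissue
comparison is within-patient, removing patient-level effects (including
germline variation) by design. A small set of unmatched embryonic
kidney (EK) samples supports unpaired comparisons against the
developmental state the rests resemble. All analyses run on beta values
(methylated fraction in [0, 1]); an M-value transform
(`log2(beta/(1-beta))`, clipped at 1e-6) is available but effect sizes
are reported on the beta scale throughout, where a difference of 0.2
means 20 percentage points of methylation.

## Moderated differential methylation

The paired contrast is a one-sample moderated t on within-patient
differences `d_gi = beta_gi(a) - beta_gi(b)`; for complete pairs this is
identical to a patient-blocked two-group linear model and far simpler to
reason about. The three-tissue analysis fits `beta ~ tissue + patient`
per probe (QR projections, fully vectorised) and tests the 2-df tissue
term; an unblocked variant is available by flag.

Variance moderation follows the standard empirical-Bayes hierarchy:
per-probe variances are modelled as scaled-F draws around a prior
(s0², d0), estimated by method of moments on log variances with a
damped-Newton trigamma inversion. Conventions deliberately match limma,
confirmed by a direct cross-check (t to 1e-15, p to 1e-10): when the
moment estimator finds no excess dispersion the prior is infinite and s0²
is the arithmetic mean of the variances; the t/F reference df `d0 + df`
is capped at the pooled residual df; exact zero variances are offset to
1e-5 times the median before estimation. Probes with any missing value
in a contrast are excluded from that fit (mirroring the
any-sample-failing-detection filter) and reported with NaN statistics.
BH adjustment is the standard step-up (via statsmodels), tested against
a hand-written implementation.

Thresholds follow the study's operating points: MVPs at FDR < 0.01,
genome-wide ANOVA significance at raw p < 5e-8 (raw by convention for
"genome-wide significance", not FDR; both are exposed).

## Probe-lasso DMR calling

Probe spacing on the array varies by two orders of magnitude between
CpG islands and open sea, so the caller sizes a per-probe window
("lasso") from the median nearest-neighbour distance within the probe's
gene-feature x CGI-relation category, floored at half the global
minimum lasso size (10 bp). "Connected" is formalised as mutual lasso
containment — each probe inside the other's window — which is symmetric
and order-independent; the prose notion of connectivity admits several
readings and this one makes the graph well-defined. Components with at
least 3 significant probes become regions, every probe inside the union
of member lassos is absorbed (so region-level significance sees the
non-significant interior), and regions whose bounds lie closer than
1 kb are merged (gap measured bound-to-bound on 0-based half-open
intervals; member sets unioned, significant counts summed). The
region p combines all member probes' one-sided p-values, aligned to the
region's direction (sign of the mean delta-beta over significant
members), by Stouffer's Z — the combiner is a package decision; nothing
canonical is implied by the workflow itself.

The implementation is required, by test, to agree exactly with an
all-pairs brute-force oracle on hundreds of random fixtures — member
sets, bounds, counts and merges.

## Reference-free cell-mixture adjustment

Bulk methylation mixes cell types linearly in beta, so a composition
difference between tissues masquerades as differential methylation.
With no reference profiles, the mixture structure is estimated from the
data: per-probe OLS on the design; SVD of the residual matrix; the top
`d` left singular vectors U span the probe-space directions along which
composition varies within tissues. Because mixture weights sum to one,
a between-tissue mean composition shift moves the coefficient vector
inside span(U), so the adjusted coefficients are
`B_adj = B - U U^T B`. (Appending the residuals' sample-space scores to
the design would change nothing — they are orthogonal to the design
columns by construction — which is why the adjustment must act in probe
space.) A fixed-loadings variant was evaluated and rejected: conditional
on U, the bootstrap badly undercovers when composition is confounded
with tissue, because the latent-direction uncertainty is real variance.

Uncertainty comes from a full-procedure bootstrap: patients resampled
with replacement (pairs kept intact; samples within groups for unpaired
designs), the entire fit — OLS, SVD, projection — repeated per
replicate. Per-probe p-values use `p = 2 P(T_u > |coef|/SE_boot)` with
the SE rescaled by `sqrt(n/(n-1))` (the textbook n-out-of-n bootstrap
bias for a mean) and `u = units - 1 - d` degrees of freedom — the
latent covariates are estimated from the same units and cost df exactly
as covariates do in cluster-robust inference. A raw resampling-fraction
mode exists but is measured to be anti-conservative here (the bootstrap
distribution is narrower than the sampling distribution), so the
t-approximation is the default. Measured on null cohorts the FPR at
p < 0.01 is ~1.4x nominal; under strong confounding the unadjusted rate
is ~9x nominal and the adjusted rate ~1.7x.

The latent dimension can be estimated by permutation parallel analysis:
observed singular values against the 95th percentile of 20
column-permuted residual matrices, counting leading values above their
threshold and stopping at the first failure. The pipeline operating
point is d = 3, matching a cohort whose residual space holds two
mixture directions (three cell types on the simplex) plus one global
array-level direction.

No DMR calling is performed on adjusted results: the adjustment yields
coefficients and p-values, not a corrected beta matrix, so regional
aggregation of corrected values is not defined.

## Unsupervised structure

Consensus clustering follows Monti: repeated subsampling of samples
(80%, 1000 resamples by default; 200-500 in the drivers), hierarchical
clustering per resample, consensus = co-clustering frequency among
co-sampled pairs, final assignment by clustering 1 - consensus, and k
chosen by the largest relative change in the consensus-CDF area unless
fixed. The default linkage is Ward on Euclidean distances: average
linkage on 1 - Pearson (the traditional methylation recipe, still
available via arguments) proved fragile to single hypervariable outlier
tumours, which seize a singleton cluster at k = 3 in roughly a third of
simulated cohorts; Ward recovers the three-group topology in all of
them.

MDS is classical Torgerson scaling (double-centred squared distances,
eigendecomposition), with axes ordered by eigenvalue and signed so each
axis's first nonzero coordinate is positive — embedding distances
reproduce Euclidean input distances exactly when the points are truly
low-dimensional. Bartlett's homogeneity test is vectorised across
probes (verified against scipy per probe to 1e-10); all-zero-variance
probes get K² = 0, p = 1 and a degenerate flag. Note Bartlett's power
at the cohort's group sizes is modest — what is reliably large is the
*asymmetry* of significant calls between a hypervariable and a stable
group, and that ratio is the reported summary. The cluster-clinical
association is a Pearson chi-square without continuity correction
(Yates by flag).

## Enrichment and the hypermethylation classifier

Feature enrichment compares the query's in-feature fraction with
equal-size draws without replacement from the post-filter probe
universe; enrichment is reported in percentage points and the empirical
p is `(1 + #{draws at least as extreme})/(1 + n_resamples)`, whose floor
at the default 100 resamples is 0.0099 — reported as P = 0.01 at two
decimals. The default reports the smaller tail (side chosen by the sign
of the enrichment); only a fixed-side p is exactly uniform under the
null, and the calibration tests use that mode. Probe membership in a
feature uses the half-open convention: a 1-based probe position `pos`
is inside `[start, end)` iff `start <= pos - 1 < end`.

The classifier computes, per region, each sample's mean beta over
member probes (NA-robust); the threshold is the reference (NR) cohort's
mean of per-sample region means plus one sample SD (ddof = 1, across
per-sample means — not across all probe x sample values), and a tumour
is called hypermethylated on strict inequality. Frequencies are
reported as "x of n" strings. Under the null (tumours drawn from the
reference distribution) the call rate is the normal upper-tail
P(X > mu + sigma) ~ 0.16, verified by simulation.

## The synthetic cohort generator

Each sample is a Dirichlet mixture of `d = 3` latent cell-type beta
profiles; betas are mixed on the beta scale (as real cell mixtures
are), then patient random effects (logit SD 0.15), a per-array global
intensity effect (logit SD 0.10), planted tissue effects and
measurement noise (logit SD 0.30) are added on the logit scale and
mapped back through the logistic — every value stays strictly in (0, 1)
and effect sizes are controllable: a planted shift is computed as the
logit offset that moves the baseline beta by the configured
delta-beta, so realised effects match configured ones to within the
Monte-Carlo tolerance of the sigmoid's curvature (~±20%).

Planted structure mirrors the study's proportions at a 20,000-probe
scale: 30 kidney-rest regions (55% hypermethylated) and 30 tumour
regions (73.6% hypomethylated), each 4-8 contiguous island probes, plus
1,000 scattered single-CpG effects per contrast — differential CpGs in
such cohorts are predominantly isolated, with only a minority forming
regions, and without the scattered component the tumour subgroup is not
separable by the unsupervised workflow. Group-2 tumours are drawn from
exactly the same distribution as their rests (no planted effects, no
extra noise); group-1 tumours (13 of 20 patients, all 9 bilateral cases
among them) carry the tumour effects and a 1.5x noise-SD multiplier.
Embryonic-kidney contrasts get 250 scattered effects carried by all
post-natal tissues. Hypermethylation loci double as feature-set members:
a configurable fraction of hyper kidney-rest loci lies inside
kilobase-scale "bivalent domain" intervals and PRC2-target intervals
(on top of random background coverage), emulating the recurrence of the
same poised developmental loci across contrasts.

Composition heterogeneity has two regimes. The default cohort uses
concentrated Dirichlet weights (sums ~12) and moderate profile
separation (logit offsets SD 1.5 at 30% of probes), so tissue signal
dominates unsupervised structure — NK, NR and both tumour groups have
distinct mean compositions, but the group-1 and group-2 mixture
distributions match their rests. The dedicated confounded fixture
(`confounded_config`) uses dispersed weights (sums ~4) and strong
profile separation (SD 3.0) with the tumour composition shifted halfway
from NR towards NK: this is the regime reference-free adjustment exists
for, and the latent space is identifiable from within-tissue
variability there. `zero_effect_config` removes all tumour effects and
the noise multiplier for null calibration.

What the generator does **not** emulate: array chemistry (type I/II
probe bias, detection failures beyond a configurable missingness rate),
FFPE degradation, normalisation artefacts, genuine genomic correlation
structure beyond planted regions, SNP-affected probes (flags are random
labels), or biological heterogeneity of real rests (intralobar vs
perilobar). Passing tests therefore demonstrate the statistical
machinery is correct and calibrated under the assumed generative
structure — not that any biological conclusion transfers to real
cohorts.

## Problem sizes and determinism

Tests and the acceptance script run cohorts at 20 trios x 20,000 probes
(5,000 probes for bootstrap-heavy deconvolution fixtures, 100-200
bootstrap replicates, 200-500 consensus resamples) — sizes at which
every statistical regime of interest is already stable. Every stochastic
operation takes an explicit seed and is bit-reproducible given it; the
pipeline report is a pure function of (inputs, config, seeds).

## Known limitations

* The reference-free adjustment's p-values are approximate; residual
  anti-conservatism of ~1.5x nominal at p < 0.01 remains under strong
  confounding (the unadjusted analysis is ~9x there).
* Lasso radii use the median nearest-neighbour distance per category;
  other density summaries would give different region boundaries at
  sparse categories.
* The consensus k-selection heuristic (max CDF-area change) is known to
  favour small k on weakly structured data; the pipeline fixes k = 3 by
  default and exposes automatic selection as an option.
* `estimate_dimension` assumes exchangeable noise within columns; heavy
  probe-wise variance heterogeneity inflates the permutation threshold
  and can under-count weak components.
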
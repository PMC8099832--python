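# Methods

## The abundance estimator

On Affymetrix-style arrays the relative DNA quantity at probe *p* in
sample *i* is expressed as the log2 ratio
`L2R_ip = log2(observed_ip / reference_p)`. For the mitochondrial
panel, the model underlying the estimator is

    L2R_ip = a_p * c_i + b_p + e_ip

with `c_i` the (log-scale) true mtDNA copy number of sample *i*, `a_p`
a probe gain, `b_p` a probe offset, and `e_ip` zero-mean noise.
Well-behaved probes have `a_p > 0`; degenerate probes can carry zero or
negative gain, which is what makes the plain median across probes
unreliable.

Calibration uses normalized off-target MT coverage from exome
sequencing (mean MT coverage over mean genomic coverage), an
established proxy for mtDNA copy number that is available on a subset
of samples. Stage 1 regresses coverage jointly on all MT probe L2R
values (intercept included, no other covariates); probes whose
coefficient reaches p < alpha (default 0.05) are selected. Stage 2
refits on the selected probes; the refit coefficients are the published
weights. The per-sample estimate is the median of the weighted values,
`mL2RMT_i = median_p(w_p * L2R_ip)`. Negative-gain probes receive
negative weights and are thereby rectified. Even-count medians use the
mean-of-middle-two convention — stated explicitly because the weighted
median over few probes is sensitive to it. Two unweighted comparators
are provided: the plain median over all MT probes and the plain median
over a configured probe subset.

Under the generative model above, the population coefficients of the
stage-1 regression have the closed form (Sherman–Morrison on the probe
covariance `aa' * var(c) + diag(s_p^2)`)

    beta_p = var(c) * (a_p / s_p^2) / (1 + var(c) * sum_q a_q^2 / s_q^2)

which the test suite uses as the independent oracle for weight
recovery.

Raw estimates are rescaled to mean 0 / sample SD 1 within each
genotyping plate (96 samples by default), absorbing plate-level
intensity shifts; plates with zero spread or a single usable sample are
set missing and logged. Standardization is idempotent, and with every
plate forced to unit sample SD the pooled sample SD of the cohort is
`sqrt((m-1)/m) ~ 0.995` for plate size m = 96 — whence the 0.99 the
cohort table shows. The autosomal summary mL2Rauto is the per-sample
median of autosomal L2R values, standardized the same way. The median
was chosen over the mean for symmetry with mL2RMT and robustness;
a mean variant is available via `statistic="mean"`.

Open choices resolved here: the calibration regression includes an
intercept and no covariates; probes are not pre-filtered before the
joint fit; coverage is used on its raw scale by default (plate
standardization absorbs scale; a z-scored option exists).

## Sample QC

Per sample: SDL2R is the sample SD of autosomal L2R values (at least
two probes required). The default exclusion is SDL2R >= 0.36; an
adaptive mode excludes at mean + 2 cohort SDs instead, which on a
Gaussian SDL2R distribution removes ~2.3%. Both modes are provided
because the fixed threshold is the two-SD rule frozen at a particular
cohort. BAF phase concordance is our concrete reading of the
phased-heterozygous-site check used by mosaic-alteration callers: at
each phased het site the deviation `e = s * (BAF - 0.5)` is aligned to
haplotype A (`s = +1` when the alternate allele is on haplotype A), and
concordance is the fraction of consecutive-site pairs whose deviations
share a non-zero sign (zero-deviation pairs skipped). Independent noise
around BAF 0.5 gives ~0.5; a consistent allelic shift (contamination,
mosaicism) pushes it toward 1. Samples above 0.52 are excluded.
Call rate below 99% excludes, as do upstream genotype-derived flags
(sex anomaly, heterozygosity outlier, ancestry, relatedness), which are
consumed as inputs rather than recomputed. A missing metric excludes
with reason `missing_metric`; exclusion is monotone in every metric.

## Derived phenotypes

The frailty index follows the Rockwood accumulation-of-deficits model:
deficits present / items answered over 49 ternary items, set missing
when fewer than 39 items (80%) were answered. The denominator uses
answered items so that sparse non-response does not deflate the index;
the 80% floor keeps it from being driven by a handful of answers.

Tertiles cut at the empirical 33.333%/66.667% quantiles
(linear-interpolation convention); boundary ties go to the lower group.
Both conventions are fixed because they decide tertile membership.
For a standard-normal exposure the lower cutoff converges to
`Phi^-1(1/3) = -0.4307`. Exposure standardization returns the mean and
sample SD used, so per-SD slopes can be mapped back to raw units.

## Associations and the two-lines test

Associations are OLS of the outcome on the z-scored exposure plus
covariates (categorical covariates expanded to indicators), fit per
stratum; the slope is per stratum-specific SD and therefore invariant
to affine rescaling of the raw exposure. Wald 95% CIs and two-sided
p-values are reported; Benjamini–Hochberg q-values (step-up, monotone,
capped at 1) control FDR across a result set.

The two-lines test fits separate OLS lines on `{x <= c}` and `{x > c}`
for every candidate cutoff c (default: a 1-unit grid across the
observed range, at least 10 observations per side) and selects the c
minimizing the total residual sum of squares. Covariates, when given,
are shared by both segment fits. The U-shape flag requires both segment
slopes significant at p < 0.05 with opposite signs. The RSS grid is a
deliberate simplification of the original two-lines proposal (which
places the breakpoint by the "Robin Hood" reallocation rule); the
candidate grid is configurable, and the joint flag's false-positive
rate on a single-slope arm of the generator is verified at <= 5%.
Optimal-split selection does inflate the joint rate for exposures whose
single slope sits near the per-segment detection boundary; the flag,
not the cutoff, should be interpreted cautiously in that regime.

Survival is handled as stated associations of follow-up time plus a
logistic model on the death flag; no formal time-to-event model is
fitted.

## PheWAS

Diagnosis events (code, ISO date) are mapped to phecodes through a
user-supplied table `code, phecode, excl_low, excl_high`, where the
exclusion interval of related diseases must contain its own phecode.
For a target phecode: cases have their first matching event strictly
after baseline and none on/before (a same-day tie counts as prevalent —
the conservative incident definition); samples with prevalent disease
are excluded entirely; non-cases with any event in the exclusion range
are removed from controls. Qualifying phecodes need more than 250 cases
(implemented as >= 251). Logistic regression on the ordinal tertile
(0/1/2) is the primary contrast; T1-vs-T2 and T3-vs-T2 probe U-shaped
risk. Fits with (quasi-)separation are skipped with the reason logged;
q-values are computed per contrast across tested phecodes.

## Variant scan

Hardy–Weinberg equilibrium is tested exactly (Levene–Haldane
conditional distribution of the heterozygote count; p sums the
probabilities of tables no more probable than the observed one),
computed with a vectorized log-gamma evaluation; monomorphic sites
return 1. Filters retain variants with MAF > 0.05, missingness < 0.02,
imputation R² > 0.6 and HWE p >= 1e-5. The scan projects covariates out
of outcome and dosages once (Frisch–Waugh–Lovell), mean-imputes missing
dosages per variant, and reports Wald t p-values at the residual
degrees of freedom. The genomic inflation factor is the median Wald
chi-square over 0.45494 (the chi-square_1 median). Clumping is greedy:
best remaining p becomes a locus lead, significant variants within 1 Mb
(configurable) join its locus, and members with dosage r² < 0.1 to the
lead are recorded as additional independent signals. Genome-wide and
suggestive thresholds are 5e-8 and 1e-5.

## The synthetic cohort generator

`synthio.simulate_cohort` draws, from a single seed:

* true log copy number `c = kink(age, sex) + beta_bmi*z(bmi) +
  beta_smoke*z(packyears) + sum_j effect_j*(dosage_j - 2 MAF_j) +
  N(0, 0.8)`. Women follow a continuous change point at 55 years
  (+0.05/y below, -0.05/y above by default — a deliberately pronounced
  kink so the change point is identifiable at cohort sizes of order
  10^4); men get a level shift (-0.05) and a steady decline (-0.06 per
  SD of age). Ages are uniform on [40, 70];
* MT probe L2R `= a_p c + b_p + batch shift + s_i * e_ip`, with gains
  U(0.5, 1.5) for clean probes and U(-1, 0] for the adversarial 25%,
  offsets N(0, 0.1), per-probe noise SD U(0.5, 1.5). The noise scale
  puts the per-probe signal-to-noise near 1, the regime in which a
  plain median degrades and calibration pays off — cleaner noise makes
  every estimator equivalent; autosomal probes are far better behaved
  (noise SD U(0.05, 0.25)) and track a small DNA-quantity factor, so
  SDL2R lands around 0.19 with a realistic exclusion tail;
* a latent per-sample DNA-quality factor that multiplies intensity
  noise (log-normally, sigma 0.3) and drives genotype missingness
  (`base 0.004`, coupled with configurable strength plus independent
  jitter), linking call rate to intensity noise exactly when the
  confounding parameter is non-zero. The recorded call rate is the
  analytic (expected) rate; realized missingness appears in the dosage
  matrix;
* normalized MT coverage `max(0, 5 + c + N(0, 0.5))` — linear in copy
  number with an intercept keeping it non-negative;
* HWE genotypes at MAFs U(0.05, 0.5), 49 deficit items with an
  age-increasing, copy-number-linked logit, incident disease over a
  10-year window with a configurable odds ratio per true-copy-number
  tertile (default 1.5, base rate 5%), blood markers with mild
  copy-number links, and background diagnosis codes.

Noise is Gaussian throughout — L2R lives on a log scale where
approximately symmetric error is reasonable. Disease onset is a single
Bernoulli draw over the follow-up window, matching the logistic PheWAS
downstream; there is no survival process, no linkage disequilibrium
structure, no read-level sequencing and no haplogroup sequence model.
Consequently, passing tests demonstrate correct recovery of the
generator's statistical structure (linear probe physics, independent
variants, logistic disease risk), not robustness to artifacts absent
from it (LD, batch-by-probe interactions, non-Gaussian intensity
tails, informative censoring).

## Problem sizes and numerical choices

The shipped tests exercise cohorts of 400–20,000 samples, 20–40 MT
probes, and up to 5,000 variants; CI-coverage checks use 100 seeds,
estimator-ordering checks 100 seeds at n = 2,000, and the null PheWAS
50 seeds of 200 phecodes at n = 1,000 — sizes at which every stated
property is comfortably identified. Medians use numpy's
mean-of-middle-two; sample SDs use ddof = 1 everywhere; plate
standardization tolerates 1e-9; rank deficiency is detected by matrix
rank and reported with the aliased (or most collinear) columns; BH ties
are handled by stable mergesort. Degenerate inputs — constant plates,
singleton plates, all-missing probes, monomorphic variants, constant
dosages, separation in logistic fits — are set missing/skipped with a
logged reason rather than raised, except where the result would be
meaningless (constant tertile input, zero-SD exposure), which raise.
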
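# mitoabund

Estimating mitochondrial DNA abundance in blood from genotyping-array
probe intensities — and testing what it is associated with.

Genotyping arrays carry a handful of probes on the mitochondrial
chromosome. The log2 ratio (L2R) of each probe's observed to reference
intensity is a noisy readout of the relative amount of mtDNA hybridized
to the array, but a plain median over MT probes is easily corrupted by
poorly behaved probes — in practice such estimates can even be
*negatively* correlated with mtDNA quantity measured by orthogonal
means. `mitoabund` implements a calibration approach: probe-level L2R
values are regressed jointly on normalized mitochondrial off-target
coverage from whole-exome sequencing (mean MT coverage / mean genomic
coverage, available for a calibration subset), probes with significant
coefficients are kept and refit, and the per-sample abundance estimate

    mL2RMT = median_p ( w_p * L2R_p ),   p over selected probes

is rescaled to mean 0 / SD 1 within each 96-well genotyping plate.
Anti-correlated probes get negative weights and are thereby rectified
rather than discarded. An autosomal analogue (mL2Rauto, the per-sample
median of autosomal L2R) summarizes overall hybridized DNA quantity and
serves as a technical covariate.

Around the estimator, the package provides the downstream machinery of
a population-scale mtDNA study:

* **sample QC** — SDL2R (per-sample SD of autosomal L2R, cutoff 0.36 or
  adaptive mean + 2 SD), B-allele-frequency phase concordance (> 0.52
  excluded), call rate (< 99% excluded), and upstream genotype flags;
* **derived phenotypes** — Rockwood frailty index (deficits present /
  deficits assessed, 49 items), per-SD exposure standardization,
  tertile discretization;
* **associations** — covariate-adjusted, optionally sex- or
  haplogroup-stratified OLS with per-SD slopes, Wald CIs and
  Benjamini–Hochberg q-values, plus a two-lines breakpoint test that
  fits separate regressions below/above an RSS-selected cutoff to
  detect sign-reversing age relationships (e.g. the pre/post-menopause
  reversal in women);
* **PheWAS** — ICD-style diagnosis events mapped to phecodes, incident
  cases only (events strictly after baseline; prevalent cases removed;
  controls cleaned of related-disease codes via phecode exclusion
  ranges), logistic regression on abundance tertiles (> 250 cases
  required), ordinal plus T1-vs-T2 / T3-vs-T2 contrasts;
* **variant scan** — HWE exact test, the standard filters (MAF > 5%,
  missingness < 2%, imputation R² > 0.6, HWE p ≥ 1e-5), per-variant
  linear association with covariate projection, genomic inflation
  λ = median χ² / 0.45494, and greedy clumping of significant variants
  into loci with independent signals at r² < 0.1 to the lead;
* **synthetic cohorts** — a generator (`mitoabund.synthio`) producing
  probe intensities, coverage, phenotypes, deficit items, diagnosis
  events and HWE genotypes with known ground truth, so every stage is
  testable without restricted data.

## Worked example

```python
import numpy as np
from mitoabund.synthio import SimulationConfig, simulate_cohort
from mitoabund.abundance import fit_probe_weights, abundance_table
from mitoabund.assoc import linear_association, two_lines_test

cohort = simulate_cohort(SimulationConfig(seed=1, n_samples=20_000))
fit = fit_probe_weights(cohort.intensity, cohort.coverage, alpha=0.05)
print(f"selected probes: {fit.table.selected.sum()} of {len(fit.table)}")

abund = abundance_table(cohort.intensity, fit,
                        cohort.phenotypes[["sample_id", "plate_id"]])
merged = cohort.phenotypes.merge(abund, on="sample_id")
for r in linear_association(merged, "ml2rmt", "bmi",
                            covariates=["age", "sex"], strata="sex"):
    print(f"bmi ({r.stratum}): slope per SD {r.slope:+.3f} "
          f"[{r.ci_low:+.3f}, {r.ci_high:+.3f}], p={r.p_value:.2e}, n={r.n}")

women = merged[merged.sex == "F"]
tl = two_lines_test(women.age, women.ml2rmt,
                    candidate_cutoffs=np.arange(45.0, 66.0))
print(f"two-lines cutoff: {tl.cutoff:.0f} y, slopes {tl.slope_below:+.4f} / "
      f"{tl.slope_above:+.4f}, U-shape: {tl.u_shape_flag}")
```

prints

```
selected probes: 35 of 40
bmi (F): slope per SD -0.056 [-0.075, -0.036], p=1.84e-08, n=10023
bmi (M): slope per SD -0.044 [-0.063, -0.025], p=5.93e-06, n=9977
two-lines cutoff: 54 y, slopes +0.0507 / -0.0586, U-shape: True
```

The calibration kept 35 of 40 MT probes (the cohort was simulated with
25% adversarial probes). Higher BMI predicts lower standardized mtDNA
abundance in both sexes (the generator's effect is −0.05 per SD), and
the two-lines test on the female arm finds an abundance rise before and
fall after an age cutoff adjacent to the generator's menopause change
point at 55 — the U-shape flag fires because both segment slopes are
significant with opposite signs.

The same stages are scriptable from the shell:

```bash
mitoabund simulate --out-dir sim --seed 1
mitoabund run --config config.yaml        # chained pipeline + manifest
```

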
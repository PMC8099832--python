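"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of a biobank-scale mtDNA-abundance
study: per-sample true log copy number shaped by age, sex (with a female
change point at the menopause age), BMI, smoking and causal variants;
MT-panel probe intensities that are linear-in-copy-number with per-probe
gain/offset/noise (including adversarial probes whose gain is negative);
exome off-target MT coverage proportional to copy number; a DNA-quality
factor coupling genotype missingness to intensity noise; questionnaire
deficit items; incident disease over a fixed follow-up window; and HWE
genotypes.

Every random draw flows from the single configured seed, so a fixed
config yields bit-identical output across runs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "SimulatedCohort", "simulate_cohort", "default_phecode_map"]

#: ICD-style code emitted for the simulated target disease and its phecode.
DISEASE_CODE = "D500"
DISEASE_PHECODE = 500.0

_HAPLOGROUPS = np.array(["H", "U", "J", "T", "K", "V", "W", "X"])
_HAPLOGROUP_FREQS = np.array([0.45, 0.15, 0.10, 0.10, 0.08, 0.05, 0.04, 0.03])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Effect sizes (``beta_*``) act on the true log copy number per SD of
    the corresponding covariate; ``pre_slope``/``post_slope`` are per
    year of age for women below/above ``menopause_age``. The kink is
    continuous at the change point. ``missingness_confounding`` couples
    a latent per-sample DNA-quality factor to both genotype missingness
    and intensity noise; at 0 the two are independent.
    """

    n_samples: int = 2000
    n_mt_probes: int = 40
    n_auto_probes: int = 60
    plate_size: int = 96
    frac_adversarial_probes: float = 0.25
    probe_noise_sd_range: tuple[float, float] = (0.5, 1.5)
    auto_probe_noise_sd_range: tuple[float, float] = (0.05, 0.25)
    probe_gain_range: tuple[float, float] = (0.5, 1.5)
    probe_offset_sd: float = 0.1
    batch_l2r_sd: float = 0.03
    batch_size: int = 4800
    beta_age: float = -0.06
    beta_sex: float = -0.05
    beta_bmi: float = -0.05
    beta_smoke: float = -0.05
    menopause_age: float = 55.0
    pre_slope: float = 0.05
    post_slope: float = -0.05
    min_age: float = 40.0
    max_age: float = 70.0
    copy_number_noise_sd: float = 0.8
    coverage_intercept: float = 5.0
    coverage_noise_sd: float = 0.5
    sample_noise_sd: float = 0.3
    base_missingness: float = 0.004
    missingness_noise_sd: float = 0.3
    missingness_confounding: float = 1.0
    n_variants: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    imputation_r2_range: tuple[float, float] = (0.4, 1.0)
    causal_variant_effects: tuple[tuple[int, float], ...] = ()
    disease_tertile_or: float = 1.5
    disease_base_rate: float = 0.05
    followup_days: int = 3650
    n_deficit_items: int = 49
    deficit_base_logit: float = -2.1
    deficit_age_slope: float = 0.04
    deficit_lcn_effect: float = -0.2
    deficit_missing_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_mt_probes": self.n_mt_probes,
            "n_auto_probes": self.n_auto_probes,
            "n_deficit_items": self.n_deficit_items,
        }
        for name, value in counts.items():
            if not (isinstance(value, (int, np.integer)) and value > 0):
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.plate_size < 2:
            raise ValueError("plate_size must be at least 2")
        if self.n_variants < 0:
            raise ValueError("n_variants must be non-negative")
        for name in ("frac_adversarial_probes", "base_missingness", "disease_base_rate", "deficit_missing_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        for name, value in dataclasses.asdict(self).items():
            flat = np.asarray(value, dtype=object).ravel() if isinstance(value, tuple) else [value]
            for v in flat:
                if isinstance(v, tuple):
                    flat2 = list(v)
                else:
                    flat2 = [v]
                for w in flat2:
                    if isinstance(w, (int, float, np.floating, np.integer)) and not math.isfinite(float(w)):
                        raise ValueError(f"config field {name} contains a non-finite value")
        lo, hi = self.probe_noise_sd_range
        if lo < 0 or hi < lo:
            raise ValueError("probe_noise_sd_range must be an ordered pair of non-negative reals")
        if self.disease_tertile_or <= 0:
            raise ValueError("disease_tertile_or must be positive")
        for idx, _eff in self.causal_variant_effects:
            if not (0 <= idx < max(self.n_variants, 1)):
                raise ValueError(f"causal variant index {idx} outside [0, n_variants)")
        if self.min_age >= self.max_age:
            raise ValueError("min_age must be below max_age")


@dataclass
class SimulatedCohort:
    """Bundle of every table produced by :func:`simulate_cohort`."""

    config: SimulationConfig
    truth: pd.DataFrame          # per-sample ground truth
    probe_truth: pd.DataFrame    # per-probe gain/offset/noise
    intensity: pd.DataFrame      # long (sample_id, probe_id, panel, l2r)
    coverage: pd.DataFrame       # (sample_id, normalized_mt_coverage)
    phenotypes: pd.DataFrame
    events: pd.DataFrame         # (sample_id, code, event_date)
    variants: pd.DataFrame       # per-variant metadata
    dosages: pd.DataFrame        # samples x variants, NaN = missing

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "truth": self.truth,
            "probe_truth": self.probe_truth,
            "intensity": self.intensity,
            "coverage": self.coverage,
            "phenotypes": self.phenotypes,
            "events": self.events,
            "variants": self.variants,
            "dosages": self.dosages,
        }


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _tertile_index(values: np.ndarray) -> np.ndarray:
    lo, hi = np.quantile(values, [1.0 / 3.0, 2.0 / 3.0])
    return np.where(values <= lo, 0, np.where(values <= hi, 1, 2))


def default_phecode_map() -> pd.DataFrame:
    """Tiny diagnosis-code -> phecode map covering the simulated codes.

    The target disease phecode carries an exclusion range so that
    related-disease control exclusion is exercised downstream.
    """
    return pd.DataFrame(
        {
            "code": [DISEASE_CODE, "D501", "I10", "J45"],
            "phecode": [DISEASE_PHECODE, 500.2, 401.0, 495.0],
            "excl_low": [500.0, 500.0, 401.0, 495.0],
            "excl_high": [500.9, 500.9, 401.9, 495.9],
        }
    )


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Draw a full synthetic cohort under ``config``.

    Per-sample true log copy number is

        c = kink(age, sex) + beta_bmi*z(bmi) + beta_smoke*z(packyears)
            + sum_j effect_j * (dosage_j - 2*MAF_j) + N(0, sd)

    where for women ``kink`` has slope ``pre_slope`` below the menopause
    age and ``post_slope`` above (continuous at the change point), and
    for men it is a level shift ``beta_sex`` plus a monotone decline
    ``beta_age`` per SD of age.  MT probe p reads
    ``l2r = gain_p*c + offset_p + batch_shift + s_i*noise``, with
    adversarial probes drawing gain from U(-1, 0].
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples

    sample_id = np.array([f"S{i:06d}" for i in range(n)])
    age = rng.uniform(config.min_age, config.max_age, size=n)
    is_female = rng.random(n) < 0.5
    sex = np.where(is_female, "F", "M")
    bmi = np.where(is_female, rng.normal(27.0, 5.1, n), rng.normal(27.8, 4.2, n))
    smoker = rng.random(n) < np.where(is_female, 0.35, 0.45)
    packyears = np.where(smoker, rng.exponential(18.0, n), 0.0)
    plate_id = np.array([f"P{i // config.plate_size:04d}" for i in range(n)])
    batch_idx = np.arange(n) // config.batch_size
    batch_id = np.array([f"B{b:03d}" for b in batch_idx])
    haplogroup = rng.choice(_HAPLOGROUPS, size=n, p=_HAPLOGROUP_FREQS)

    # latent DNA quality: high q = clean sample (low noise, low missingness)
    quality = rng.standard_normal(n)
    noise_mult = np.exp(config.sample_noise_sd * (-quality))
    missingness = config.base_missingness * np.exp(
        config.missingness_confounding * (-quality)
        + config.missingness_noise_sd * rng.standard_normal(n)
    )
    missingness = np.clip(missingness, 0.0, 0.5)
    call_rate = 1.0 - missingness

    # genotypes under HWE
    m = config.n_variants
    maf = rng.uniform(*config.maf_range, size=m)
    geno = rng.binomial(2, maf[None, :], size=(n, m)).astype(float)
    variant_id = np.array([f"rs{i:06d}" for i in range(m)])
    pos = 100_000 + 10_000 * np.arange(m)
    imputation_r2 = rng.uniform(*config.imputation_r2_range, size=m)

    # true log copy number
    kink = np.where(
        is_female,
        np.where(
            age < config.menopause_age,
            config.pre_slope * (age - config.menopause_age),
            config.post_slope * (age - config.menopause_age),
        ),
        config.beta_sex + config.beta_age * (age - age.mean()) / max(age.std(ddof=1), 1e-12),
    )
    lcn = (
        kink
        + config.beta_bmi * _zscore(bmi)
        + config.beta_smoke * _zscore(packyears)
    )
    for idx, effect in config.causal_variant_effects:
        lcn = lcn + effect * (geno[:, idx] - 2.0 * maf[idx])
    lcn = lcn + rng.normal(0.0, config.copy_number_noise_sd, n)

    # probes
    n_mt = config.n_mt_probes
    n_adv = int(round(config.frac_adversarial_probes * n_mt))
    adversarial = np.zeros(n_mt, dtype=bool)
    adversarial[:n_adv] = True
    gain = np.empty(n_mt)
    gain[adversarial] = -rng.uniform(0.0, 1.0, n_adv)  # U(-1, 0]
    gain[~adversarial] = rng.uniform(*config.probe_gain_range, n_mt - n_adv)
    mt_offset = rng.normal(0.0, config.probe_offset_sd, n_mt)
    mt_noise_sd = rng.uniform(*config.probe_noise_sd_range, n_mt)

    auto_offset = rng.normal(0.0, config.probe_offset_sd, config.n_auto_probes)
    auto_noise_sd = rng.uniform(*config.auto_probe_noise_sd_range, config.n_auto_probes)

    n_batches = batch_idx.max() + 1
    batch_shift = rng.normal(0.0, config.batch_l2r_sd, n_batches)[batch_idx]

    # autosomal DNA quantity tracks sample quality (hybridization efficiency)
    auto_quantity = 0.1 * quality

    mt_l2r = (
        lcn[:, None] * gain[None, :]
        + mt_offset[None, :]
        + batch_shift[:, None]
        + noise_mult[:, None] * rng.normal(0.0, 1.0, (n, n_mt)) * mt_noise_sd[None, :]
    )
    auto_l2r = (
        auto_quantity[:, None]
        + auto_offset[None, :]
        + batch_shift[:, None]
        + noise_mult[:, None]
        * rng.normal(0.0, 1.0, (n, config.n_auto_probes))
        * auto_noise_sd[None, :]
    )

    mt_probe_id = np.array([f"MT_{i:04d}" for i in range(n_mt)])
    auto_probe_id = np.array([f"AUTO_{i:04d}" for i in range(config.n_auto_probes)])

    intensity = pd.concat(
        [
            pd.DataFrame(
                {
                    "sample_id": np.repeat(sample_id, n_mt),
                    "probe_id": np.tile(mt_probe_id, n),
                    "panel": "MT",
                    "l2r": mt_l2r.ravel(),
                }
            ),
            pd.DataFrame(
                {
                    "sample_id": np.repeat(sample_id, config.n_auto_probes),
                    "probe_id": np.tile(auto_probe_id, n),
                    "panel": "autosomal",
                    "l2r": auto_l2r.ravel(),
                }
            ),
        ],
        ignore_index=True,
    )

    probe_truth = pd.DataFrame(
        {
            "probe_id": np.concatenate([mt_probe_id, auto_probe_id]),
            "panel": ["MT"] * n_mt + ["autosomal"] * config.n_auto_probes,
            "gain": np.concatenate([gain, np.ones(config.n_auto_probes)]),
            "offset": np.concatenate([mt_offset, auto_offset]),
            "noise_sd": np.concatenate([mt_noise_sd, auto_noise_sd]),
            "adversarial": np.concatenate(
                [adversarial, np.zeros(config.n_auto_probes, dtype=bool)]
            ),
        }
    )

    coverage_vals = np.maximum(
        0.0, config.coverage_intercept + lcn + rng.normal(0.0, config.coverage_noise_sd, n)
    )
    coverage = pd.DataFrame({"sample_id": sample_id, "normalized_mt_coverage": coverage_vals})

    # genotype missingness realised on hard calls
    miss_mask = rng.random((n, m)) < missingness[:, None]
    dosage_vals = geno.copy()
    dosage_vals[miss_mask] = np.nan
    dosages = pd.DataFrame(dosage_vals, index=pd.Index(sample_id, name="sample_id"), columns=variant_id)
    variants = pd.DataFrame(
        {
            "variant_id": variant_id,
            "chrom": "1",
            "pos": pos,
            "maf": maf,
            "imputation_r2": imputation_r2,
        }
    )

    # deficits: age-increasing logit, individual propensity, copy-number link
    propensity = rng.standard_normal(n)
    item_shift = rng.normal(0.0, 0.3, config.n_deficit_items)
    logits = (
        config.deficit_base_logit
        + config.deficit_age_slope * (age - 55.0)
        + 0.5 * propensity
        + config.deficit_lcn_effect * lcn
    )[:, None] + item_shift[None, :]
    deficits = (rng.random((n, config.n_deficit_items)) < _sigmoid(logits)).astype(float)
    deficits[rng.random((n, config.n_deficit_items)) < config.deficit_missing_rate] = np.nan

    # incident disease via tertiles of the true copy number
    tert = _tertile_index(lcn)
    base_logit = math.log(config.disease_base_rate / (1.0 - config.disease_base_rate))
    p_disease = _sigmoid(base_logit + math.log(config.disease_tertile_or) * tert)
    disease = rng.random(n) < p_disease
    onset_day = np.where(disease, rng.integers(1, config.followup_days + 1, n), -1)

    baseline_offset = rng.integers(0, 731, n)
    baseline0 = date(2008, 1, 1)
    baseline_dates = np.array(
        [(baseline0 + timedelta(days=int(d))).isoformat() for d in baseline_offset]
    )

    event_rows: list[tuple[str, str, str]] = []
    for i in np.flatnonzero(disease):
        d = date.fromisoformat(baseline_dates[i]) + timedelta(days=int(onset_day[i]))
        event_rows.append((sample_id[i], DISEASE_CODE, d.isoformat()))
    # background diagnoses unrelated to the target phecode
    for code in ("I10", "J45"):
        hit = rng.random(n) < 0.05
        offs = rng.integers(-1000, config.followup_days, n)
        for i in np.flatnonzero(hit):
            d = date.fromisoformat(baseline_dates[i]) + timedelta(days=int(offs[i]))
            event_rows.append((sample_id[i], code, d.isoformat()))
    events = pd.DataFrame(event_rows, columns=["sample_id", "code", "event_date"])
    events = events.sort_values(["sample_id", "event_date"], kind="mergesort").reset_index(drop=True)

    # blood markers with mild copy-number links (innate cells down, lymphocytes up)
    wbc = np.maximum(1.0, 6.9 - 0.2 * lcn + rng.normal(0.0, 1.8, n))
    lymph_pct = np.clip(29.0 + 1.0 * lcn + rng.normal(0.0, 7.0, n), 2.0, 90.0)
    neut_pct = np.clip(58.0 - 1.0 * lcn + rng.normal(0.0, 8.0, n), 5.0, 95.0)
    platelet = np.maximum(30.0, 252.0 + 3.0 * lcn + rng.normal(0.0, 58.0, n))
    pc1 = rng.standard_normal(n)
    pc2 = rng.standard_normal(n)

    fi_answered = np.sum(~np.isnan(deficits), axis=1)
    fi = np.where(
        fi_answered > 0, np.nansum(deficits, axis=1) / np.maximum(fi_answered, 1), np.nan
    )
    followup_years = config.followup_days / 365.25
    death_p = _sigmoid(-4.0 + 0.04 * (age - 55.0) + 2.0 * np.nan_to_num(fi) - 0.1 * lcn)
    death_flag = rng.random(n) < death_p
    survival_time = np.where(death_flag, rng.uniform(0.0, followup_years, n), followup_years)

    phenotypes = pd.DataFrame(
        {
            "sample_id": sample_id,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "packyears": packyears,
            "plate_id": plate_id,
            "batch_id": batch_id,
            "call_rate": call_rate,
            "haplogroup": haplogroup,
            "baseline_date": baseline_dates,
            "wbc": wbc,
            "neut_pct": neut_pct,
            "lymph_pct": lymph_pct,
            "platelet": platelet,
            "pc1": pc1,
            "pc2": pc2,
            "survival_time": survival_time,
            "death_flag": death_flag.astype(int),
        }
    )
    for j in range(config.n_deficit_items):
        phenotypes[f"fi_item_{j + 1:02d}"] = deficits[:, j]

    truth = pd.DataFrame(
        {
            "sample_id": sample_id,
            "true_log_copy_number": lcn,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "packyears": packyears,
            "plate_id": plate_id,
            "batch_id": batch_id,
            "call_rate": call_rate,
            "quality": quality,
            "noise_multiplier": noise_mult,
            "true_tertile": tert,
            "incident_disease": disease.astype(int),
            "onset_day": onset_day,
        }
    )

    return SimulatedCohort(
        config=config,
        truth=truth,
        probe_truth=probe_truth,
        intensity=intensity,
        coverage=coverage,
        phenotypes=phenotypes,
        events=events,
        variants=variants,
        dosages=dosages,
    )
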
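"""Sample-level quality control on intensity and genotype metrics.

Exclusions follow array-QC practice: samples with noisy intensities
(SDL2R, the per-sample SD of autosomal L2R values), evidence of mosaic
or contaminated signal (BAF phase concordance), low genotyping call
rate, or upstream genotype-derived flags (sex anomaly, heterozygosity
outlier, ancestry, relatedness) are removed before any association
analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .abundance import _pivot_l2r

logger = logging.getLogger(__name__)

__all__ = ["QCThresholds", "compute_sdl2r", "compute_baf_concordance", "apply_exclusions"]

_FLAG_REASONS = {
    "sex_anomaly": ("sex_anomaly", True),
    "het_outlier": ("het_outlier", True),
    "ancestry_pass": ("ancestry", False),
    "unrelated_pass": ("relatedness", False),
}


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion cutoffs.

    ``sdl2r_mode='fixed'`` excludes at SDL2R >= ``sdl2r_max`` (default
    0.36); ``'adaptive'`` excludes at mean + ``adaptive_n_sd`` cohort
    SDs instead, the rule the fixed value approximates.
    """

    sdl2r_max: float = 0.36
    sdl2r_mode: str = "fixed"  # or "adaptive"
    adaptive_n_sd: float = 2.0
    baf_concordance_max: float = 0.52  # exclude strictly above
    call_rate_min: float = 0.99       # exclude strictly below

    def __post_init__(self):
        if self.sdl2r_mode not in {"fixed", "adaptive"}:
            raise ValueError("sdl2r_mode must be 'fixed' or 'adaptive'")


def compute_sdl2r(intensity: pd.DataFrame) -> pd.Series:
    """Per-sample sample-SD of autosomal L2R values (missing if <2 probes)."""
    wide = _pivot_l2r(intensity, panel="autosomal")
    arr = wide.to_numpy()
    n_obs = np.sum(~np.isnan(arr), axis=1)
    out = pd.Series(np.nan, index=wide.index, name="sdl2r")
    ok = n_obs >= 2
    if ok.any():
        out[ok] = pd.DataFrame(arr[ok]).std(axis=1, ddof=1).to_numpy()
    return out


def compute_baf_concordance(baf, phase) -> float:
    """Adjacent-pair sign agreement of phase-aligned BAF deviations.

    At each phased heterozygous site (ordered by position) the deviation
    ``e = s * (BAF - 0.5)`` is aligned to haplotype A: ``s = +1`` when
    the alternate allele sits on haplotype A (``phase='hapA_alt'``),
    ``-1`` otherwise.  Concordance is the fraction of consecutive pairs
    whose deviations share a non-zero sign; pairs containing a zero
    deviation are skipped.  High concordance indicates a consistent
    allelic shift (mosaicism or contamination); independent noise around
    BAF = 0.5 gives ~0.5.  Returns NaN with fewer than two usable sites
    or no usable pair.
    """
    baf = np.asarray(baf, dtype=float)
    phase = np.asarray(phase)
    if baf.shape != phase.shape:
        raise ValueError("baf and phase must have equal length")
    valid = {"hapA_ref", "hapA_alt"}
    if not set(np.unique(phase)) <= valid:
        raise ValueError(f"phase entries must be one of {sorted(valid)}")
    if np.any((baf < 0) | (baf > 1)):
        raise ValueError("BAF values must lie in [0, 1]")
    s = np.where(phase == "hapA_alt", 1.0, -1.0)
    e = s * (baf - 0.5)
    keep = ~np.isnan(e)
    e = e[keep]
    if e.size < 2:
        return float("nan")
    sign = np.sign(e)
    a, b = sign[:-1], sign[1:]
    usable = (a != 0) & (b != 0)
    if not usable.any():
        return float("nan")
    return float(np.mean(a[usable] == b[usable]))


def apply_exclusions(metrics: pd.DataFrame, thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Flag samples for exclusion and record every reason.

    ``metrics`` has one row per sample with columns ``sample_id``,
    ``call_rate``, ``sdl2r``, ``baf_concordance`` and optionally the
    boolean flags ``sex_anomaly``, ``het_outlier``, ``ancestry_pass``,
    ``unrelated_pass`` (absent flag columns are treated as passing).  A
    missing metric excludes the sample with reason ``missing_metric``.
    Exclusion is monotone: worsening any metric never rescues a sample.
    """
    thresholds = thresholds or QCThresholds()
    out = metrics.copy()
    n = len(out)

    sdl2r = out["sdl2r"].astype(float)
    if thresholds.sdl2r_mode == "adaptive":
        cut = float(sdl2r.mean() + thresholds.adaptive_n_sd * sdl2r.std(ddof=1))
        logger.info("adaptive SDL2R cutoff: %.4f", cut)
    else:
        cut = thresholds.sdl2r_max

    reasons: list[list[str]] = [[] for _ in range(n)]

    def _mark(mask, reason):
        for i in np.flatnonzero(mask.to_numpy()):
            reasons[i].append(reason)

    for col in ("call_rate", "sdl2r", "baf_concordance"):
        if col not in out.columns:
            raise ValueError(f"metrics table lacks required column {col!r}")
    _mark(out[["call_rate", "sdl2r", "baf_concordance"]].isna().any(axis=1), "missing_metric")
    _mark(sdl2r >= cut, "sdl2r")
    _mark(out["baf_concordance"].astype(float) > thresholds.baf_concordance_max, "baf_concordance")
    _mark(out["call_rate"].astype(float) < thresholds.call_rate_min, "call_rate")
    for col, (reason, bad_value) in _FLAG_REASONS.items():
        if col in out.columns:
            _mark(out[col].fillna(not bad_value).astype(bool) == bad_value, reason)

    out["exclusion_reasons"] = [";".join(r) for r in reasons]
    out["excluded"] = [bool(r) for r in reasons]
    out["sdl2r_cutoff_applied"] = cut
    return out
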
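"""Variant-level association scan for mtDNA abundance.

Covers the genetic arm of the pipeline at desk scale: Hardy–Weinberg
testing, the standard variant filters (MAF > 5%, missingness < 2%,
imputation R^2 > 0.6, HWE p >= 1e-5), per-variant linear association of
the abundance estimate with additive dosages, the genomic inflation
factor (median Wald chi-square over the chi-square_1 median 0.45494),
and greedy clumping of significant variants into loci with independent
signals at r^2 < 0.1 to the lead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "hwe_test",
    "genomic_inflation",
    "VariantFilters",
    "variant_metrics",
    "filter_variants",
    "gwas_scan",
    "clump_signals",
    "GENOME_WIDE_P",
    "SUGGESTIVE_P",
    "CHI2_1_MEDIAN",
]

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 1e-5
CHI2_1_MEDIAN = 0.45494


def genomic_inflation(chi2_values) -> float:
    """Genomic inflation factor: median Wald chi-square / 0.45494.

    Scale-equivariant in the chi-square values; ~1 under the null.
    """
    chi2 = np.asarray(chi2_values, dtype=float)
    chi2 = chi2[~np.isnan(chi2)]
    if chi2.size == 0:
        raise ValueError("no chi-square values supplied")
    if np.any(chi2 < 0):
        raise ValueError("chi-square values must be non-negative")
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy–Weinberg equilibrium p-value for one biallelic site.

    Uses the Levene–Haldane distribution of the heterozygote count
    conditional on the allele counts: the p-value sums the
    probabilities of all genotype tables no more probable than the
    observed one.  Symmetric in the homozygote labels; monomorphic
    sites return 1.
    """
    counts = (n_aa, n_ab, n_bb)
    if any(c < 0 for c in counts):
        raise ValueError(f"genotype counts must be non-negative, got {counts}")
    if sum(counts) == 0:
        raise ValueError("total genotype count must be positive")
    n = sum(counts)
    na = 2 * n_aa + n_ab      # allele A count
    nb = 2 * n_bb + n_ab
    if na == 0 or nb == 0:
        return 1.0
    rare = min(na, nb)
    # heterozygote count shares the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    logp = (
        gammaln(n + 1)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
        + hets * np.log(2.0)
        + gammaln(na + 1)
        + gammaln(nb + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    obs = probs[hets == n_ab][0]
    # tolerate float round-off when comparing table probabilities
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-10)].sum()))


@dataclass(frozen=True)
class VariantFilters:
    maf_min: float = 0.05          # retain strictly above
    missingness_max: float = 0.02  # retain strictly below
    imputation_r2_min: float = 0.6 # retain strictly above
    hwe_p_min: float = 1e-5        # retain at or above


def variant_metrics(dosages: pd.DataFrame) -> pd.DataFrame:
    """MAF, missingness and HWE p from a hard-call dosage matrix.

    ``dosages`` is samples x variants with entries 0/1/2 or NaN.  The
    HWE test rounds dosages to genotype classes.
    """
    arr = dosages.to_numpy(dtype=float)
    n = arr.shape[0]
    n_missing = np.isnan(arr).sum(axis=0)
    missingness = n_missing / n
    af = np.nanmean(arr, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    hwe_p = np.empty(arr.shape[1])
    for j in range(arr.shape[1]):
        g = arr[:, j]
        g = g[~np.isnan(g)]
        counts = np.bincount(np.rint(g).astype(int), minlength=3)
        hwe_p[j] = hwe_test(int(counts[0]), int(counts[1]), int(counts[2]))
    return pd.DataFrame(
        {
            "variant_id": dosages.columns,
            "maf": maf,
            "missingness": missingness,
            "hwe_p": hwe_p,
        }
    )


def filter_variants(
    variants: pd.DataFrame, thresholds: VariantFilters | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the variant QC filters; return retained rows and per-filter counts.

    Idempotent and order-invariant.  ``variants`` needs columns ``maf``,
    ``missingness``, ``imputation_r2`` and ``hwe_p``.
    """
    t = thresholds or VariantFilters()
    fails = {
        "maf": ~(variants["maf"] > t.maf_min),
        "missingness": ~(variants["missingness"] < t.missingness_max),
        "imputation_r2": ~(variants["imputation_r2"] > t.imputation_r2_min),
        "hwe": ~(variants["hwe_p"] >= t.hwe_p_min),
    }
    report = {name: int(mask.sum()) for name, mask in fails.items()}
    keep = ~np.logical_or.reduce([m.to_numpy() for m in fails.values()])
    report["retained"] = int(keep.sum())
    return variants.loc[keep].reset_index(drop=True), report


@dataclass
class GwasSummary:
    table: pd.DataFrame            # variant_id, chrom, pos, slope, se, p, chi2
    lambda_gc: float
    n_samples: int
    loci: list[dict] = field(default_factory=list)


def gwas_scan(
    dosages: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    variants: pd.DataFrame | None = None,
) -> GwasSummary:
    """Per-variant OLS of the abundance estimate on additive dosage.

    Covariates (complete rows only) are projected out of both outcome
    and dosages (Frisch–Waugh–Lovell), so each variant costs one inner
    product.  Missing dosages are mean-imputed per variant; variants
    left constant are skipped with a warning.  Wald p-values use the
    t distribution at the residual degrees of freedom; lambda_GC is the
    median Wald chi-square divided by 0.45494.
    """
    common = dosages.index.intersection(outcome.index)
    if covariates is not None:
        covariates = covariates.reindex(common)
        complete = covariates.notna().all(axis=1) & outcome.reindex(common).notna()
    else:
        complete = outcome.reindex(common).notna()
    idx = common[complete]
    y = outcome.reindex(idx).to_numpy(dtype=float)
    G = dosages.reindex(idx).to_numpy(dtype=float)
    n = y.size
    if covariates is not None and covariates.shape[1]:
        from .assoc import _design

        C = _design(covariates.loc[idx], list(covariates.columns)).to_numpy()
        Z = np.column_stack([np.ones(n), C])
    else:
        Z = np.ones((n, 1))
    Q, _ = np.linalg.qr(Z)
    y_r = y - Q @ (Q.T @ y)

    col_mean = np.nanmean(G, axis=0)
    nan_mask = np.isnan(G)
    G = np.where(nan_mask, col_mean[None, :], G)
    G_r = G - Q @ (Q.T @ G)

    gg = np.einsum("ij,ij->j", G_r, G_r)
    constant = gg <= 1e-12
    if constant.any():
        logger.warning("gwas_scan: %d variants constant after adjustment; skipped", int(constant.sum()))
    gy = G_r.T @ y_r
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = gy / gg
    dof = n - Z.shape[1] - 1
    rss = (y_r @ y_r) - slope * gy
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / gg)
        tstat = slope / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    chi2 = tstat**2

    table = pd.DataFrame(
        {
            "variant_id": dosages.columns,
            "slope": slope,
            "se": se,
            "p": p,
            "chi2": chi2,
        }
    )
    table.loc[constant, ["slope", "se", "p", "chi2"]] = np.nan
    if variants is not None:
        table = variants[["variant_id", "chrom", "pos"]].merge(table, on="variant_id", how="right")
    ok = table["chi2"].notna()
    lam = genomic_inflation(table.loc[ok, "chi2"]) if ok.any() else float("nan")
    return GwasSummary(table=table, lambda_gc=lam, n_samples=n)


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        return float("nan")
    r = np.corrcoef(a[ok], b[ok])[0, 1]
    return float(r * r)


def clump_signals(
    summary: pd.DataFrame,
    dosages: pd.DataFrame,
    p_threshold: float = GENOME_WIDE_P,
    r2_threshold: float = 0.1,
    window_bp: int = 1_000_000,
) -> list[dict]:
    """Greedy clumping of significant variants into loci.

    Repeatedly takes the remaining variant with the smallest p as a
    locus lead, sweeps every remaining significant variant within
    ``window_bp`` on the same chromosome into its locus, and records as
    additional independent signals the locus members with dosage
    r^2 < ``r2_threshold`` to the lead (all members are genome-wide
    significant by construction).
    """
    sig = summary[(summary["p"] < p_threshold) & summary["p"].notna()].copy()
    sig = sig.sort_values(["p", "variant_id"], kind="mergesort")
    remaining = sig
    loci: list[dict] = []
    while len(remaining):
        lead = remaining.iloc[0]
        same = remaining[
            (remaining["chrom"] == lead["chrom"])
            & ((remaining["pos"] - lead["pos"]).abs() <= window_bp)
        ]
        lead_dos = dosages[lead["variant_id"]].to_numpy(dtype=float)
        independent = [lead["variant_id"]]
        for vid in same["variant_id"]:
            if vid == lead["variant_id"]:
                continue
            r2 = _pairwise_r2(lead_dos, dosages[vid].to_numpy(dtype=float))
            if np.isnan(r2) or r2 < r2_threshold:
                independent.append(vid)
        loci.append(
            {
                "lead_variant": lead["variant_id"],
                "chrom": lead["chrom"],
                "pos": int(lead["pos"]),
                "lead_p": float(lead["p"]),
                "n_members": int(len(same)),
                "independent_signals": independent,
            }
        )
        remaining = remaining[~remaining["variant_id"].isin(same["variant_id"])]
    return loci
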
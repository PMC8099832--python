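"""mtDNA abundance estimation from array probe intensities.

The estimator proceeds in three steps:

1. probe weights are learned by regressing normalized exome off-target
   MT coverage jointly on the L2R values of all MT probes, keeping the
   probes whose coefficients are significant and refitting on those;
2. each sample's abundance (mL2RMT) is the median of its weighted
   per-probe L2R values (or the plain median for the unweighted
   variants used as comparators);
3. raw estimates are rescaled to mean 0 / SD 1 within each genotyping
   plate, absorbing plate-level intensity shifts.

The autosomal counterpart (mL2Rauto) summarizes overall hybridized DNA
quantity and is computed with the same median-and-standardize recipe.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "compute_l2r",
    "fit_probe_weights",
    "compute_ml2rmt",
    "compute_ml2rauto",
    "standardize_by_plate",
]


def compute_l2r(observed, reference, probe_id=None, sample_id=None):
    """log2 ratio of observed to reference probe intensity.

    Scale-invariant: ``compute_l2r(k*x, k*y) == compute_l2r(x, y)`` for
    any k > 0.  Non-positive intensities are rejected with a message
    naming the offending probe/sample when those are supplied.
    """
    observed = np.asarray(observed, dtype=float)
    reference = np.asarray(reference, dtype=float)
    bad = (observed <= 0) | (reference <= 0) | ~np.isfinite(observed) | ~np.isfinite(reference)
    if np.any(bad):
        where = ""
        if probe_id is not None or sample_id is not None:
            idx = np.flatnonzero(np.atleast_1d(bad))[0]
            probe = np.atleast_1d(probe_id)[idx] if probe_id is not None else "?"
            sample = np.atleast_1d(sample_id)[idx] if sample_id is not None else "?"
            where = f" (first offender: probe {probe}, sample {sample})"
        raise ValueError(f"intensities must be strictly positive and finite{where}")
    return np.log2(observed / reference)


def _pivot_l2r(intensity: pd.DataFrame, panel: str | None = None) -> pd.DataFrame:
    """Long (sample_id, probe_id, l2r) -> wide samples x probes."""
    df = intensity
    if panel is not None and "panel" in df.columns:
        df = df[df["panel"] == panel]
    if df.duplicated(["sample_id", "probe_id"]).any():
        raise ValueError("duplicate (sample_id, probe_id) pairs in intensity table")
    if "l2r" not in df.columns:
        df = df.assign(
            l2r=compute_l2r(
                df["observed_intensity"], df["reference_intensity"],
                probe_id=df["probe_id"].to_numpy(), sample_id=df["sample_id"].to_numpy(),
            )
        )
    return df.pivot(index="sample_id", columns="probe_id", values="l2r")


@dataclass
class ProbeWeightFit:
    """Two-stage probe-weight fit: selection then refit.

    ``table`` has one row per probe: ``probe_id, weight, p_value,
    selected``; ``p_value`` is the stage-1 joint-regression p-value used
    for selection, ``weight`` the stage-2 refit coefficient (0 for
    unselected probes).
    """

    table: pd.DataFrame
    intercept: float
    alpha: float

    @property
    def selected_probes(self) -> list[str]:
        return self.table.loc[self.table["selected"], "probe_id"].tolist()


def fit_probe_weights(
    intensity: pd.DataFrame,
    coverage: pd.DataFrame,
    alpha: float = 0.05,
    zscore_coverage: bool = False,
) -> ProbeWeightFit:
    """Learn per-probe weights from the coverage calibration subset.

    Stage 1 regresses coverage jointly on all MT probe L2R values (with
    intercept, no covariates); probes with coefficient p < ``alpha`` are
    selected.  Stage 2 refits on the selected probes only; the refit
    coefficients are the weights.  Only samples present in both tables
    enter the fit; calibration rows with missing L2R are dropped (and
    logged).
    """
    wide = _pivot_l2r(intensity, panel="MT")
    cov = coverage.set_index("sample_id")["normalized_mt_coverage"]
    common = wide.index.intersection(cov.index)
    X = wide.loc[common]
    y = cov.loc[common].astype(float)
    complete = X.notna().all(axis=1) & y.notna()
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("fit_probe_weights: dropped %d calibration rows with missing values", n_dropped)
    X, y = X.loc[complete], y.loc[complete]
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"calibration subset has {X.shape[0]} samples for {X.shape[1]} probes; "
            "need more samples than probes"
        )
    if zscore_coverage:
        y = (y - y.mean()) / y.std(ddof=1)

    design = sm.add_constant(X.to_numpy(), has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        corr = np.corrcoef(X.to_numpy(), rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            "rank-deficient probe design; most collinear pair: "
            f"{X.columns[i]} and {X.columns[j]} (r={corr[i, j]:.4f})"
        )
    stage1 = sm.OLS(y.to_numpy(), design).fit()
    pvals = pd.Series(stage1.pvalues[1:], index=X.columns)
    selected = pvals < alpha
    if not selected.any():
        raise ValueError(
            "no probe reached the selection threshold; enlarge the calibration set "
            f"(alpha={alpha}, smallest p={pvals.min():.3g})"
        )

    sel_cols = X.columns[selected]
    design2 = sm.add_constant(X[sel_cols].to_numpy(), has_constant="add")
    stage2 = sm.OLS(y.to_numpy(), design2).fit()
    weights = pd.Series(0.0, index=X.columns)
    weights[sel_cols] = stage2.params[1:]

    table = pd.DataFrame(
        {
            "probe_id": X.columns,
            "weight": weights.to_numpy(),
            "p_value": pvals.to_numpy(),
            "selected": selected.to_numpy(),
        }
    ).reset_index(drop=True)
    return ProbeWeightFit(table=table, intercept=float(stage2.params[0]), alpha=alpha)


def compute_ml2rmt(
    intensity: pd.DataFrame,
    weights: ProbeWeightFit | pd.DataFrame | None = None,
    method: str = "weighted",
    subset: list[str] | None = None,
) -> pd.DataFrame:
    """Per-sample mtDNA abundance: median of (weighted) MT probe L2R.

    ``method='weighted'`` takes the median over selected probes of
    weight x L2R; ``'unweighted_all'`` the plain median over every MT
    probe; ``'unweighted_subset'`` the plain median over ``subset``.
    Even-count medians use the mean-of-middle-two convention.  Samples
    with no usable probe get a missing estimate and a flag.
    """
    wide = _pivot_l2r(intensity, panel="MT")
    if method == "weighted":
        if weights is None:
            raise ValueError("method 'weighted' requires a fitted ProbeWeightTable")
        table = weights.table if isinstance(weights, ProbeWeightFit) else weights
        sel = table.loc[table["selected"]]
        if sel.empty:
            raise ValueError("weight table has no selected probes")
        missing_cols = set(sel["probe_id"]) - set(wide.columns)
        if missing_cols:
            raise ValueError(f"selected probes absent from intensity table: {sorted(missing_cols)}")
        w = sel.set_index("probe_id")["weight"]
        values = wide[w.index].to_numpy() * w.to_numpy()[None, :]
    elif method == "unweighted_all":
        values = wide.to_numpy()
    elif method == "unweighted_subset":
        if not subset:
            raise ValueError("method 'unweighted_subset' requires a probe subset")
        missing_cols = set(subset) - set(wide.columns)
        if missing_cols:
            raise ValueError(f"subset probes absent from intensity table: {sorted(missing_cols)}")
        values = wide[list(subset)].to_numpy()
    else:
        raise ValueError(f"unknown method {method!r}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows handled below
        est = np.nanmedian(values, axis=1)
    all_missing = np.isnan(values).all(axis=1)
    est[all_missing] = np.nan
    if all_missing.any():
        logger.warning("compute_ml2rmt: %d samples have no usable probe", int(all_missing.sum()))
    return pd.DataFrame(
        {
            "sample_id": wide.index.to_numpy(),
            "ml2rmt_raw": est,
            "all_probes_missing": all_missing,
            "method": method,
        }
    )


def compute_ml2rauto(intensity: pd.DataFrame, statistic: str = "median") -> pd.DataFrame:
    """Per-sample autosomal DNA abundance: median (default) of autosomal L2R."""
    if statistic not in {"median", "mean"}:
        raise ValueError("statistic must be 'median' or 'mean'")
    wide = _pivot_l2r(intensity, panel="autosomal")
    func = np.nanmedian if statistic == "median" else np.nanmean
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est = func(wide.to_numpy(), axis=1)
    all_missing = np.isnan(wide.to_numpy()).all(axis=1)
    est[all_missing] = np.nan
    return pd.DataFrame({"sample_id": wide.index.to_numpy(), "ml2rauto_raw": est})


def standardize_by_plate(
    values: pd.Series | np.ndarray,
    plate_ids: pd.Series | np.ndarray,
) -> pd.Series:
    """Rescale to mean 0 / sample SD 1 within each genotyping plate.

    Plates whose SD is 0 (or that hold a single non-missing value) get
    all values set missing and are logged.  Idempotent: a standardized
    vector restandardizes to itself.
    """
    x = pd.Series(np.asarray(values, dtype=float))
    plates = pd.Series(np.asarray(plate_ids), index=x.index)
    out = pd.Series(np.nan, index=x.index)
    for plate, idx in x.groupby(plates).groups.items():
        vals = x.loc[idx]
        ok = vals.notna()
        if ok.sum() < 2:
            logger.warning("plate %s has <2 non-missing samples; values set missing", plate)
            continue
        sd = vals[ok].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            logger.warning("plate %s has zero intensity spread; values set missing", plate)
            continue
        out.loc[idx] = (vals - vals[ok].mean()) / sd
    if isinstance(values, pd.Series):
        out.index = values.index
        out.name = values.name
    return out


def abundance_table(
    intensity: pd.DataFrame,
    weights: ProbeWeightFit | pd.DataFrame | None,
    plate_ids: pd.DataFrame | pd.Series,
    method: str = "weighted",
    subset: list[str] | None = None,
    auto_statistic: str = "median",
) -> pd.DataFrame:
    """Convenience wrapper: raw + plate-standardized mL2RMT and mL2Rauto.

    ``plate_ids`` is either a Series indexed by sample_id or a frame
    with ``sample_id`` and ``plate_id`` columns.
    """
    if isinstance(plate_ids, pd.DataFrame):
        plate_ids = plate_ids.set_index("sample_id")["plate_id"]
    mt = compute_ml2rmt(intensity, weights, method=method, subset=subset).set_index("sample_id")
    auto = compute_ml2rauto(intensity, statistic=auto_statistic).set_index("sample_id")
    out = mt.join(auto, how="left")
    plates = plate_ids.reindex(out.index)
    out["ml2rmt"] = standardize_by_plate(out["ml2rmt_raw"], plates)
    out["ml2rauto"] = standardize_by_plate(out["ml2rauto_raw"], plates)
    return out.reset_index()
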
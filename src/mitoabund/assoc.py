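"""Per-SD linear associations, BH FDR, and the two-lines breakpoint test.

Associations report the slope of the outcome per standard deviation of
the exposure with a Wald 95% CI, optionally covariate-adjusted and
stratified (by sex, haplogroup, ...).  The two-lines test fits separate
regressions below and above a breakpoint chosen by residual-sum-of-
squares minimization over a candidate grid and flags a U (or inverted-U)
shape when both segment slopes are significant with opposite signs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .phenotypes import standardize_exposure

__all__ = ["AssociationResult", "linear_association", "bh_fdr", "TwoLinesResult", "two_lines_test"]


@dataclass(frozen=True)
class AssociationResult:
    outcome: str
    exposure: str
    stratum: str
    slope: float       # per SD of the exposure
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    exposure_sd: float
    q_value: float = float("nan")


def _design(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Covariate design matrix; categorical columns become indicators."""
    if not covariates:
        return pd.DataFrame(index=df.index)
    parts = []
    for col in covariates:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            parts.append(pd.get_dummies(s, prefix=col, drop_first=True, dtype=float))
        else:
            parts.append(s.astype(float).to_frame(col))
    return pd.concat(parts, axis=1)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify an aliased column by testing each column's marginal contribution
        aliased = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                aliased.append(names[j])
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")


def linear_association(
    data: pd.DataFrame,
    outcome: str,
    exposure: str,
    covariates: list[str] | None = None,
    strata: str | list[str] | None = None,
) -> list[AssociationResult]:
    """OLS of ``outcome`` on the z-scored ``exposure`` plus covariates.

    One result per stratum (plus one for 'all' when ``strata`` is
    None).  The exposure is standardized within each stratum, so the
    slope is per stratum-specific SD and invariant to affine rescaling
    of the raw exposure.
    """
    covariates = covariates or []
    if strata is None:
        groups = [("all", data)]
    else:
        strata_cols = [strata] if isinstance(strata, str) else list(strata)
        groups = [
            ("/".join(map(str, np.atleast_1d(key))), sub)
            for key, sub in data.groupby(strata_cols, observed=True)
        ]
    results = []
    for name, sub in groups:
        cols = [outcome, exposure] + covariates
        sub = sub.dropna(subset=cols)
        if len(sub) < len(covariates) + 3:
            continue
        z, _, sd = standardize_exposure(sub[exposure].to_numpy())
        cov = _design(sub, covariates)
        X = np.column_stack([np.ones(len(sub)), z] + ([cov.to_numpy()] if len(cov.columns) else []))
        names = ["const", exposure] + list(cov.columns)
        _check_rank(X, names)
        fit = sm.OLS(sub[outcome].to_numpy(dtype=float), X).fit()
        ci = fit.conf_int(alpha=0.05)
        results.append(
            AssociationResult(
                outcome=outcome,
                exposure=exposure,
                stratum=name,
                slope=float(fit.params[1]),
                ci_low=float(ci[1][0]),
                ci_high=float(ci[1][1]),
                p_value=float(fit.pvalues[1]),
                n=int(len(sub)),
                exposure_sd=sd,
            )
        )
    return results


def results_table(results: list[AssociationResult], fdr: bool = True) -> pd.DataFrame:
    """Stack association results; optionally add BH q-values across rows."""
    df = pd.DataFrame([vars(r) for r in results])
    if fdr and len(df):
        df["q_value"] = bh_fdr(df["p_value"].to_numpy())
    return df


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass(frozen=True)
class TwoLinesResult:
    cutoff: float
    slope_below: float
    slope_above: float
    p_below: float
    p_above: float
    u_shape_flag: bool
    n_below: int
    n_above: int
    rss: float


def _segment_fit(x, y, cov):
    X = np.column_stack([np.ones(x.size), x] + ([cov] if cov is not None and cov.shape[1] else []))
    fit = sm.OLS(y, X).fit()
    return fit


def two_lines_test(
    x,
    y,
    covariates: pd.DataFrame | np.ndarray | None = None,
    candidate_cutoffs=None,
    min_side: int = 10,
) -> TwoLinesResult:
    """Breakpoint regression: separate lines below and above a cutoff.

    For each candidate cutoff c, OLS is fit on {x <= c} and {x > c}
    (each with the shared covariates); the cutoff minimizing the total
    residual sum of squares is selected.  ``u_shape_flag`` is raised
    when both segment slopes are significant at p < 0.05 with opposite
    signs.  Candidates leaving fewer than ``min_side`` points on either
    side are skipped; by default candidates walk a 1-unit grid across
    the observed range.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    else:
        cov = None
    keep = ~np.isnan(x) & ~np.isnan(y)
    if cov is not None:
        keep &= ~np.isnan(cov).any(axis=1)
        cov = cov[keep]
    x, y = x[keep], y[keep]
    if candidate_cutoffs is None:
        candidate_cutoffs = np.arange(np.ceil(x.min()), np.floor(x.max()) + 1.0)
    candidate_cutoffs = np.asarray(candidate_cutoffs, dtype=float)

    best = None
    for c in candidate_cutoffs:
        below = x <= c
        if below.sum() < min_side or (~below).sum() < min_side:
            continue
        fit_b = _segment_fit(x[below], y[below], cov[below] if cov is not None else None)
        fit_a = _segment_fit(x[~below], y[~below], cov[~below] if cov is not None else None)
        rss = float(fit_b.ssr + fit_a.ssr)
        if best is None or rss < best[0]:
            best = (rss, c, fit_b, fit_a, int(below.sum()), int((~below).sum()))
    if best is None:
        raise ValueError(
            f"no candidate cutoff leaves at least {min_side} observations on both sides"
        )
    rss, c, fit_b, fit_a, n_b, n_a = best
    slope_b, slope_a = float(fit_b.params[1]), float(fit_a.params[1])
    p_b, p_a = float(fit_b.pvalues[1]), float(fit_a.pvalues[1])
    return TwoLinesResult(
        cutoff=float(c),
        slope_below=slope_b,
        slope_above=slope_a,
        p_below=p_b,
        p_above=p_a,
        u_shape_flag=bool(p_b < 0.05 and p_a < 0.05 and slope_b * slope_a < 0),
        n_below=n_b,
        n_above=n_a,
        rss=rss,
    )
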
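"""Phecode-based PheWAS with incident case / clean-control logic.

Diagnosis events (ICD-style code + date) are mapped to phecodes.  For
each phecode, cases are samples whose first matching event falls
strictly after their baseline date; samples with a matching event on or
before baseline (prevalent disease) are excluded entirely, and samples
with any event in the phecode's exclusion range of related diseases are
removed from the control pool.  Qualifying phecodes (more than
``min_cases`` cases, default 250) are tested by logistic regression of
case status on the mtDNA-abundance tertile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .assoc import _design, bh_fdr

logger = logging.getLogger(__name__)

__all__ = ["PhecodeMap", "build_case_control", "run_phewas"]

CASE, CONTROL, EXCLUDED = "case", "control", "excluded"


@dataclass
class PhecodeMap:
    """Diagnosis-code -> phecode map with per-phecode exclusion ranges.

    Backed by a table with columns ``code, phecode, excl_low,
    excl_high``; the exclusion interval always contains its own phecode
    so cases of the related-disease group never leak into controls.
    """

    table: pd.DataFrame

    def __post_init__(self):
        req = {"code", "phecode", "excl_low", "excl_high"}
        missing = req - set(self.table.columns)
        if missing:
            raise ValueError(f"phecode map lacks columns: {sorted(missing)}")
        t = self.table
        bad = ~((t["excl_low"] <= t["phecode"]) & (t["phecode"] <= t["excl_high"]))
        if bad.any():
            raise ValueError(
                f"exclusion range must contain its own phecode; offending codes: "
                f"{t.loc[bad, 'code'].tolist()}"
            )

    @property
    def phecodes(self) -> list[float]:
        return sorted(self.table["phecode"].unique())

    def exclusion_range(self, phecode: float) -> tuple[float, float]:
        rows = self.table[self.table["phecode"] == phecode]
        if rows.empty:
            raise KeyError(f"phecode {phecode} not in map")
        return float(rows["excl_low"].iloc[0]), float(rows["excl_high"].iloc[0])


def build_case_control(
    events: pd.DataFrame,
    phecode_map: PhecodeMap,
    baseline_dates: pd.Series,
    phecode: float,
) -> pd.Series:
    """Assign every sample to case / control / excluded for one phecode.

    * case: first event mapping to the phecode strictly after baseline,
      and none on/before baseline;
    * excluded: any matching event on/before baseline (prevalent; a
      same-day tie counts as prevalent), or — among non-cases — any
      event in the phecode's related-disease exclusion range at any
      time;
    * control: everyone else.

    ``baseline_dates`` is indexed by sample_id; every sample must have
    one.  The result is invariant to event-row ordering.
    """
    if phecode not in set(phecode_map.table["phecode"]):
        raise KeyError(f"phecode {phecode} absent from the phecode map")
    excl_low, excl_high = phecode_map.exclusion_range(phecode)

    baseline = pd.to_datetime(baseline_dates)
    if baseline.isna().any():
        raise ValueError("every sample needs a parseable baseline date")

    ev = events.merge(phecode_map.table[["code", "phecode"]], on="code", how="inner")
    ev = ev[ev["sample_id"].isin(baseline.index)]
    ev = ev.assign(event_date=pd.to_datetime(ev["event_date"]))
    ev = ev.assign(baseline=baseline.reindex(ev["sample_id"]).to_numpy())

    target = ev[ev["phecode"] == phecode]
    prevalent = set(target.loc[target["event_date"] <= target["baseline"], "sample_id"])
    incident = set(target.loc[target["event_date"] > target["baseline"], "sample_id"])
    cases = incident - prevalent

    in_range = ev[(ev["phecode"] >= excl_low) & (ev["phecode"] <= excl_high)]
    related = set(in_range["sample_id"])

    status = pd.Series(CONTROL, index=baseline.index, name="status")
    status[list(related - cases)] = EXCLUDED
    status[list(prevalent)] = EXCLUDED
    status[list(cases)] = CASE
    return status


def _fit_logit(y: np.ndarray, X: np.ndarray):
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # separation warnings handled below
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
    except Exception as err:  # separation, singular design
        return None, str(err)
    if not np.isfinite(fit.bse).all() or np.any(fit.bse > 50):
        return None, "quasi-separation (unstable standard errors)"
    return fit, None


def run_phewas(
    tertiles: pd.Series,
    assignments: dict[float, pd.Series],
    covariates: pd.DataFrame | None = None,
    min_cases: int = 251,
) -> pd.DataFrame:
    """Tertile-exposure PheWAS over pre-built case/control assignments.

    ``tertiles`` holds labels 'T1'/'T2'/'T3' indexed by sample_id.  The
    primary contrast codes the tertile ordinally (0/1/2); the secondary
    contrasts compare T1 vs T2 and T3 vs T2 (the U-shape check).
    Phecodes with fewer than ``min_cases`` cases are skipped ("more
    than 250 cases" -> default 251); fits that separate are skipped
    with the reason logged.  BH q-values are computed per contrast
    across tested phecodes.
    """
    ordinal = tertiles.map({"T1": 0.0, "T2": 1.0, "T3": 2.0})
    rows = []
    for phecode, status in assignments.items():
        modeled = status[status != EXCLUDED]
        y_all = (modeled == CASE).astype(float)
        n_cases = int(y_all.sum())
        if n_cases < min_cases:
            logger.info("phecode %s skipped: %d cases < %d", phecode, n_cases, min_cases)
            continue
        for contrast in ("ordinal", "T1_vs_T2", "T3_vs_T2"):
            if contrast == "ordinal":
                expo = ordinal.reindex(modeled.index)
            elif contrast == "T1_vs_T2":
                lab = tertiles.reindex(modeled.index)
                expo = lab.map({"T1": 1.0, "T2": 0.0})
            else:
                lab = tertiles.reindex(modeled.index)
                expo = lab.map({"T3": 1.0, "T2": 0.0})
            keep = expo.notna()
            if covariates is not None:
                cov = covariates.reindex(modeled.index)
                keep &= cov.notna().all(axis=1)
                cov_design = _design(cov[keep], list(cov.columns)).to_numpy()
            else:
                cov_design = np.empty((int(keep.sum()), 0))
            y = y_all[keep].to_numpy()
            X = np.column_stack([np.ones(y.size), expo[keep].to_numpy(), cov_design])
            fit, reason = _fit_logit(y, X)
            if fit is None:
                logger.warning("phecode %s contrast %s skipped: %s", phecode, contrast, reason)
                continue
            beta, se = float(fit.params[1]), float(fit.bse[1])
            rows.append(
                {
                    "phecode": phecode,
                    "contrast": contrast,
                    "n_cases": int(y.sum()),
                    "n_controls": int(y.size - y.sum()),
                    "odds_ratio_per_tertile": float(np.exp(beta)),
                    "ci_low": float(np.exp(beta - 1.959964 * se)),
                    "ci_high": float(np.exp(beta + 1.959964 * se)),
                    "p_value": float(fit.pvalues[1]),
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q_value"] = np.nan
    for contrast, idx in out.groupby("contrast").groups.items():
        out.loc[idx, "q_value"] = bh_fdr(out.loc[idx, "p_value"].to_numpy())
    return out.sort_values(["contrast", "phecode"], kind="mergesort").reset_index(drop=True)
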
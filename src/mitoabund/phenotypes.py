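"""Derived phenotypes: frailty index, exposure z-scores, tertiles.

The frailty index follows the Rockwood accumulation-of-deficits model:
the fraction of health deficits present among the deficits assessed.
Tertile discretization and per-SD standardization back the association
and PheWAS stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "frailty_index",
    "TertileSpec",
    "tertile_discretize",
    "standardize_exposure",
]

N_DEFICIT_ITEMS = 49


def frailty_index(items, min_answered: int = 39, n_items: int = N_DEFICIT_ITEMS):
    """Rockwood frailty index from ternary deficit items.

    ``items`` is an (n_samples, n_items) array (or a single row) with
    entries 0 (deficit absent), 1 (present) or NaN (not answered).  The
    index is deficits present / items answered, missing when fewer than
    ``min_answered`` items were answered (default 39 = 80% of 49).
    Order of items is irrelevant.
    """
    arr = np.asarray(items, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != n_items:
        raise ValueError(f"expected {n_items} deficit items, got {arr.shape[1]}")
    finite = ~np.isnan(arr)
    if not np.isin(arr[finite], (0.0, 1.0)).all():
        bad = arr[finite][~np.isin(arr[finite], (0.0, 1.0))][0]
        raise ValueError(f"deficit items must be 0, 1 or missing; got {bad!r}")
    answered = finite.sum(axis=1)
    with np.errstate(invalid="ignore"):
        fi = np.nansum(arr, axis=1) / answered
    fi[answered < min_answered] = np.nan
    return float(fi[0]) if single else fi


@dataclass(frozen=True)
class TertileSpec:
    """Empirical tertile cutoffs: T1 <= lower < T2 <= upper < T3."""

    lower_cutoff: float
    upper_cutoff: float

    def assign(self, values) -> pd.Series:
        x = pd.Series(np.asarray(values, dtype=float))
        labels = pd.Series(pd.NA, index=x.index, dtype="object")
        labels[x <= self.lower_cutoff] = "T1"
        labels[(x > self.lower_cutoff) & (x <= self.upper_cutoff)] = "T2"
        labels[x > self.upper_cutoff] = "T3"
        return labels


def tertile_discretize(values) -> tuple[TertileSpec, pd.Series]:
    """Split a distribution into near-equal thirds.

    Cutoffs sit at the empirical 33.333% and 66.667% quantiles
    (linear-interpolation convention); boundary ties go to the lower
    group.  Missing values get a missing label.  A constant input has
    no meaningful tertiles and is rejected.
    """
    x = np.asarray(values, dtype=float)
    finite = x[~np.isnan(x)]
    if finite.size < 3:
        raise ValueError("need at least 3 non-missing values for tertiles")
    if np.nanmin(finite) == np.nanmax(finite):
        raise ValueError("all values identical; tertiles undefined")
    lo, hi = np.quantile(finite, [1.0 / 3.0, 2.0 / 3.0])
    spec = TertileSpec(lower_cutoff=float(lo), upper_cutoff=float(hi))
    return spec, spec.assign(values)


def standardize_exposure(values) -> tuple[np.ndarray, float, float]:
    """z-score an exposure over the analysis subset.

    Returns ``(z, mean, sd)`` so a per-SD slope can be mapped back to
    raw units (slope_raw = slope_per_sd / sd).  Sample SD (ddof=1);
    zero spread is rejected.
    """
    x = np.asarray(values, dtype=float)
    finite = x[~np.isnan(x)]
    if finite.size < 2:
        raise ValueError("need at least 2 non-missing values to standardize")
    mean = float(finite.mean())
    sd = float(finite.std(ddof=1))
    if sd == 0:
        raise ValueError("exposure has zero standard deviation")
    return (x - mean) / sd, mean, sd
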
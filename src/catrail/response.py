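"""Dose-response analysis: viability vs calcium, one-phase exponential decay.

The viability-vs-calcium relationship is summarized by the one-phase decay
family

    y(x) = (y0 − plateau) · exp(−k·x) + plateau

with y0 the viability at zero calcium, plateau the asymptotic (saturated)
viability, and k the decay rate per µM.  Fitting is ordinary least squares via
``scipy.optimize.curve_fit`` with bounds k ∈ [0, 100], plateau ∈ [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["DecayFit", "one_phase_decay", "fit_one_phase_decay", "condition_table"]


def one_phase_decay(x, y0, plateau, k):
    return (y0 - plateau) * np.exp(-k * np.asarray(x, dtype=float)) + plateau


@dataclass(frozen=True)
class DecayFit:
    y0: float
    plateau: float
    k: float
    rss: float
    residuals: np.ndarray
    covariance: np.ndarray
    converged: bool
    message: str = ""

    def predict(self, x):
        return one_phase_decay(x, self.y0, self.plateau, self.k)

    def as_dict(self) -> dict:
        return {
            "y0": self.y0,
            "plateau": self.plateau,
            "k": self.k,
            "rss": self.rss,
            "converged": self.converged,
        }


def fit_one_phase_decay(x, y) -> DecayFit:
    """Least-squares one-phase-decay fit of viability (%) against calcium (µM)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct calcium values")
    # initialization: y0 from the top of the data, plateau from the bottom,
    # rate from the scale of the x values
    med = float(np.median(x[x > 0])) if (x > 0).any() else 1.0
    p0 = (float(y.max()), float(y.min()), 1.0 / med)
    bounds = ([-np.inf, 0.0, 0.0], [np.inf, 100.0, 100.0])
    try:
        popt, pcov = curve_fit(one_phase_decay, x, y, p0=p0, bounds=bounds, maxfev=10000)
        converged, message = True, ""
    except RuntimeError as exc:  # non-convergence: report, do not hide
        return DecayFit(
            y0=float("nan"), plateau=float("nan"), k=float("nan"),
            rss=float("nan"), residuals=np.full_like(y, np.nan),
            covariance=np.full((3, 3), np.nan), converged=False, message=str(exc),
        )
    resid = y - one_phase_decay(x, *popt)
    return DecayFit(
        y0=float(popt[0]), plateau=float(popt[1]), k=float(popt[2]),
        rss=float(np.sum(resid**2)), residuals=resid, covariance=pcov,
        converged=converged, message=message,
    )


def condition_table(results) -> "pd.DataFrame":
    """Summary table of population runs sharing a TRAIL dose, sorted by calcium.

    Duplicate condition labels are kept and flagged, never silently merged.
    """
    import pandas as pd

    if not results:
        raise ValueError("no population results given")
    doses = {r.condition.trail_ng_per_ml for r in results}
    if len(doses) > 1:
        raise ValueError(f"results mix TRAIL doses: {sorted(doses)}")
    rows = []
    for r in results:
        apop = r.apoptosis_times
        momp = np.array([f.momp_time_h if f.momp_time_h is not None else np.nan for f in r.fates])
        rows.append(
            {
                "condition": r.condition.label,
                "calcium_um": r.condition.calcium_um,
                "trail_ng_per_ml": r.condition.trail_ng_per_ml,
                "viability_percent": r.viability_percent,
                "mean_apoptosis_time_h": float(np.nanmean(apop)) if np.isfinite(apop).any() else np.nan,
                "mean_momp_time_h": float(np.nanmean(momp)) if np.isfinite(momp).any() else np.nan,
                "n_cells": len(r.fates),
                "seed": r.spec.seed,
            }
        )
    df = pd.DataFrame(rows).sort_values("calcium_um", kind="stable").reset_index(drop=True)
    df["duplicate_label"] = df["condition"].duplicated(keep=False)
    return df
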
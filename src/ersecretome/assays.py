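"""Closed-form assay computations.

Scratch-wound recovery, echocardiographic fractional area change, ddCt
relative qPCR quantification, the two-arm ER-stress inducibility call, the
four-parameter logistic (4PL) dose-response fit with EC50, and the
heparinase-release difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger("ersecretome")


def scratch_recovery(area_0h: float, area_16h: float) -> float:
    """Percent scratch closure: 100 * (area_0h - area_16h) / area_0h."""
    if area_0h <= 0 or area_16h < 0:
        raise ValueError("areas must be positive (0 h) and nonnegative (16 h)")
    if area_16h > area_0h:
        logger.warning("scratch_recovery: cell-free area grew; negative recovery")
    return 100.0 * (area_0h - area_16h) / area_0h


def fractional_area_change(lveda: float, lvesa: float) -> float:
    """Echocardiographic FAC: 100 * (LVEDA - LVESA) / LVEDA."""
    if lveda <= 0:
        raise ValueError("LVEDA must be positive")
    if lvesa > lveda:
        logger.warning("fractional_area_change: LVESA exceeds LVEDA (nonphysiological)")
    return 100.0 * (lveda - lvesa) / lveda


def heparinase_released(
    abundance_with: float, abundance_without: float, tissue_mass: float
) -> float:
    """Heparan-sulfate-bound protein per mg tissue: (with - without) / mass.

    May be negative for noisy measurements; returned with a warning rather
    than clipped.
    """
    if tissue_mass <= 0:
        raise ValueError("tissue mass must be positive")
    released = (abundance_with - abundance_without) / tissue_mass
    if released < 0:
        logger.warning("heparinase_released: negative release (%g), measurement noise", released)
    return released


# ---------------------------------------------------------------------------
# ddCt
# ---------------------------------------------------------------------------

def ddct_fold_change(
    table: pd.DataFrame,
    reference_gene: str = "GAPDH",
    control_condition: str = "control",
) -> pd.DataFrame:
    """Relative qPCR quantification by the 2^-ddCt method.

    Per condition, dCt = mean Ct(gene) - mean Ct(reference); ddCt relative
    to the control condition; fold = 2^-ddCt.  Conditions lacking the
    reference gene are reported as missing.  Uses replicate-mean Ct
    (unpaired plate design).
    """
    if reference_gene not in set(table["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} absent")
    if control_condition not in set(table["condition"]):
        raise ValueError(f"control condition {control_condition!r} absent")
    mean_ct = table.groupby(["gene", "condition"])["ct"].mean()

    rows = []
    conditions = table["condition"].unique()
    genes = [g for g in table["gene"].unique() if g != reference_gene]
    for gene in genes:
        d_control = None
        if (gene, control_condition) in mean_ct and (reference_gene, control_condition) in mean_ct:
            d_control = mean_ct[(gene, control_condition)] - mean_ct[(reference_gene, control_condition)]
        for cond in conditions:
            if (
                d_control is None
                or (gene, cond) not in mean_ct
                or (reference_gene, cond) not in mean_ct
            ):
                logger.warning("ddct_fold_change: missing data for %s / %s", gene, cond)
                rows.append({"gene": gene, "condition": cond, "fold_change": float("nan")})
                continue
            dct = mean_ct[(gene, cond)] - mean_ct[(reference_gene, cond)]
            rows.append(
                {"gene": gene, "condition": cond, "fold_change": float(2.0 ** -(dct - d_control))}
            )
    return pd.DataFrame(rows)


def inducibility_call(fold_tg: float, fold_tm: float, threshold: float = 2.0) -> str:
    """Two-arm ER-stress inducibility classification.

    With fold changes under two independent ER-stress inducers (e.g.
    thapsigargin and tunicamycin): ``induced`` iff both >= threshold,
    ``repressed`` iff both <= 1/threshold, ``partial`` iff exactly one
    >= threshold, else ``unchanged``.
    """
    if fold_tg <= 0 or fold_tm <= 0 or threshold <= 0:
        raise ValueError("folds and threshold must be positive")
    hi_tg, hi_tm = fold_tg >= threshold, fold_tm >= threshold
    if hi_tg and hi_tm:
        return "induced"
    if fold_tg <= 1.0 / threshold and fold_tm <= 1.0 / threshold:
        return "repressed"
    if hi_tg or hi_tm:
        return "partial"
    return "unchanged"


# ---------------------------------------------------------------------------
# four-parameter logistic dose-response
# ---------------------------------------------------------------------------

@dataclass
class FourPLFit:
    bottom: float
    top: float
    ec50: float
    hill: float
    residual_norm: float

    def predict(self, dose):
        dose = np.asarray(dose, float)
        return self.bottom + (self.top - self.bottom) / (1.0 + (self.ec50 / dose) ** self.hill)


class FitConvergenceError(RuntimeError):
    def __init__(self, message: str, best_residual: float, starts_tried: int):
        super().__init__(message)
        self.best_residual = best_residual
        self.starts_tried = starts_tried


def fit_4pl(dose, response) -> FourPLFit:
    """Least-squares 4PL fit r(d) = bottom + (top-bottom)/(1 + (ec50/d)^hill).

    Fitted on log10 dose internally for conditioning with multi-start
    initialization over the dose range and Hill slopes {0.5, 1, 2} of both
    signs; the reported EC50 is on the linear scale with bottom <= top
    after canonical reordering.  A flat response raises a convergence error
    rather than returning a spurious EC50.
    """
    dose = np.asarray(dose, float)
    response = np.asarray(response, float)
    if len(dose) < 5:
        raise ValueError("need at least 5 dose points")
    if (dose <= 0).any():
        raise ValueError("doses must be positive")
    if np.log10(dose.max() / dose.min()) < 2:
        raise ValueError("doses must span at least two log-decades")

    span = float(np.ptp(response))
    scale = span if span > 0 else 1.0
    if span < 1e-12 * max(1.0, float(np.abs(response).max())):
        raise FitConvergenceError("flat response, EC50 unidentifiable", float("inf"), 0)

    logd = np.log10(dose)

    def residuals(params):
        bottom, top, log_ec50, hill = params
        with np.errstate(over="ignore"):
            pred = bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - logd) * hill))
        return pred - response

    lo, hi = float(response.min()), float(response.max())
    best = None
    starts = 0
    for log_ec50_0 in np.linspace(logd.min(), logd.max(), 5):
        for hill0 in (0.5, 1.0, 2.0, -0.5, -1.0, -2.0):
            starts += 1
            try:
                sol = least_squares(
                    residuals,
                    x0=[lo, hi, log_ec50_0, hill0],
                    method="lm",
                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None or not np.isfinite(best.cost):
        raise FitConvergenceError("4PL fit failed to converge", float("inf"), starts)

    bottom, top, log_ec50, hill = best.x
    if abs(hill) < 1e-6:
        raise FitConvergenceError(
            "fitted Hill slope ~ 0: response flat, EC50 unidentifiable",
            float(np.sqrt(2 * best.cost)), starts,
        )
    if bottom > top:  # canonical ordering: increasing-response parametrization
        bottom, top, hill = top, bottom, -hill
    return FourPLFit(
        bottom=float(bottom), top=float(top), ec50=float(10.0 ** log_ec50),
        hill=float(hill), residual_norm=float(np.sqrt(2 * best.cost)),
    )
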
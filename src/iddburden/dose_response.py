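"""Dose-response linking median urinary iodine (MUIC) to goiter rate (TGR).

The conversion assumes a power law TGR = alpha * MUIC**beta, fitted by
ordinary least squares after taking natural logs of both variables:
ln(TGR) = ln(alpha) + beta * ln(MUIC).  For iodine-deficient populations
beta is negative — goiter prevalence falls as iodine status improves.

A published reference model (alpha = 11049, beta = -1.63), estimated
from 24 countries with contemporaneous school-age TGR and MUIC surveys,
ships as :data:`REFERENCE_MODEL` so the conversion step runs without any
survey data.  Under that model an MUIC of 100 ug/L implies a TGR of
about 6.1%, consistent with the long-standing observation that
populations above 100 ug/L rarely show endemic goiter.
"""

from __future__ import annotations

import dataclasses
import json
import math
from collections.abc import Sequence
from enum import Enum
from pathlib import Path

import numpy as np
import statsmodels.api as sm

from .records import SurveyPoint


@dataclasses.dataclass(frozen=True)
class PowerFit:
    """Fitted power-law coefficients with log-scale diagnostics.

    ``alpha`` is the TGR (%) at MUIC = 1 ug/L; ``beta`` the elasticity
    of TGR with respect to MUIC.  Diagnostics are computed on the
    log-log scale on which the model is linear: ``r_squared_log`` is the
    OLS coefficient of determination, ``residual_sd_log`` the residual
    standard error (ddof = 2), and ``beta_se`` the standard error of the
    slope (0 when n = 2, where the line interpolates exactly).
    """

    alpha: float
    beta: float
    r_squared_log: float = 1.0
    n_points: int = 2
    residual_sd_log: float = 0.0
    beta_se: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.n_points < 2:
            raise ValueError("a power fit needs at least 2 points")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PowerFit":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


#: The published 24-country conversion model, TGR = 11049 * MUIC**-1.63.
REFERENCE_MODEL = PowerFit(alpha=11049.0, beta=-1.63, n_points=24)


class IodineStatusClass(str, Enum):
    """Population iodine status from MUIC: deficient / optimal / above."""

    DEFICIENT = "deficient"
    OPTIMAL = "optimal"
    ABOVE_OPTIMAL = "above_optimal"


#: Optimal population iodine status is an MUIC of 100-299 ug/L.
DEFAULT_THRESHOLDS = (100.0, 299.0)


def fit_power_model(points: Sequence[SurveyPoint]) -> PowerFit:
    """Fit TGR = alpha * MUIC**beta by OLS on natural logs.

    Requires at least two points, all strictly positive in both
    coordinates, and at least two distinct MUIC values (otherwise the
    slope is indeterminate).
    """
    if len(points) < 2:
        raise ValueError("need at least 2 survey points to fit a power model")
    muic = np.array([p.muic_ug_per_l for p in points], dtype=float)
    tgr = np.array([p.tgr_percent for p in points], dtype=float)
    if np.any(muic <= 0) or np.any(tgr <= 0):
        raise ValueError("all survey points must be strictly positive (log scale)")
    x = np.log(muic)
    y = np.log(tgr)
    if np.allclose(x, x[0]):
        raise ValueError("all MUIC values identical: slope is indeterminate")

    res = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = res.params
    n = len(points)
    # statsmodels reports NaN diagnostics at n == 2 (zero residual df);
    # the two-point line interpolates exactly.
    if n == 2:
        r2, resid_sd, beta_se = 1.0, 0.0, 0.0
    else:
        r2 = float(res.rsquared)
        resid_sd = float(np.sqrt(res.ssr / (n - 2)))
        beta_se = float(res.bse[1])
    return PowerFit(
        alpha=float(np.exp(intercept)),
        beta=float(slope),
        r_squared_log=r2,
        n_points=n,
        residual_sd_log=resid_sd,
        beta_se=beta_se,
    )


def predict_tgr(fit: PowerFit, muic: float) -> float:
    """Predicted goiter prevalence (%) at a given MUIC, clipped to [0, 100].

    TGR is a prevalence, so predictions are truncated at 100% for MUIC
    values small enough that the raw power law exceeds it.
    """
    if muic <= 0:
        raise ValueError("muic must be positive")
    raw = fit.alpha * muic**fit.beta
    return float(min(max(raw, 0.0), 100.0))


def classify_iodine_status(
    muic: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> IodineStatusClass:
    """Classify population iodine status from MUIC (ug/L).

    Below the lower threshold (default 100) the population is
    deficient; between the thresholds inclusive (default 100-299) it is
    optimal; above, iodine intake exceeds the optimal range.
    """
    if muic <= 0:
        raise ValueError("muic must be positive")
    lower, upper = thresholds
    if not math.isfinite(muic):
        raise ValueError("muic must be finite")
    if muic < lower:
        return IodineStatusClass.DEFICIENT
    if muic <= upper:
        return IodineStatusClass.OPTIMAL
    return IodineStatusClass.ABOVE_OPTIMAL
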
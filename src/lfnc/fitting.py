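"""Power-law model of effective FiO2 versus minute ventilation.

Effective FiO2 decays toward the room-air floor as minute ventilation grows;
per cannula flow the relationship is summarized as

    FiO2(MV) = 21 + k * MV^(-a),   k > 0, a > 0.

The fit minimizes squared residuals on the original FiO2 scale (R^2 is
reported on that scale); a log-log linear regression of (FiO2 - 21) on MV
provides the starting values only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

ROOM_AIR_PERCENT = 21.0
#: points closer than this (pp) to the room-air floor are excluded from the
#: log-space initialization (log of ~zero); they stay in the nonlinear fit
FLOOR_EXCLUSION_PP = 0.05

K_BOUNDS = (1e-12, 1e7)
A_BOUNDS = (1e-12, 5.0)


class DegenerateFitError(ValueError):
    """Too few points above the room-air floor to identify the power law."""


@dataclass(frozen=True)
class PowerFitResult:
    """Fitted FiO2(MV) = 21 + k * MV^(-a) for one cannula flow."""

    k: float
    a: float
    r2: float
    n_points: int
    flow_l_min: float | None = None

    def predict(self, mv_ml_min) -> np.ndarray:
        """Model prediction at the given minute ventilation(s)."""
        mv = np.asarray(mv_ml_min, dtype=float)
        return ROOM_AIR_PERCENT + self.k * mv ** (-self.a)


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot on the given scale."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values are all identical (zero total variance)")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def fit_power_law(
    mv_values, fio2_values, flow_l_min: float | None = None
) -> PowerFitResult:
    """Least-squares fit of FiO2 = 21 + k * MV^(-a) in original residual space.

    Raises :class:`DegenerateFitError` when fewer than three points lie above
    the room-air floor (within ``FLOOR_EXCLUSION_PP``): the power law is then
    unidentifiable.
    """
    mv = np.asarray(mv_values, dtype=float)
    fio2 = np.asarray(fio2_values, dtype=float)
    if mv.shape != fio2.shape or mv.size < 3:
        raise ValueError("mv_values and fio2_values must have equal length >= 3")
    if np.any(mv <= 0):
        raise ValueError("minute ventilation must be positive")

    above = fio2 > ROOM_AIR_PERCENT + FLOOR_EXCLUSION_PP
    if np.count_nonzero(above) < 3:
        raise DegenerateFitError(
            "fewer than 3 points above the 21% room-air floor; power law unidentifiable"
        )

    # log-log initialization on the points clearly above the floor
    log_mv = np.log(mv[above])
    log_ex = np.log(fio2[above] - ROOM_AIR_PERCENT)
    slope, intercept = np.polyfit(log_mv, log_ex, 1)
    k0 = float(np.clip(np.exp(intercept), *K_BOUNDS))
    a0 = float(np.clip(-slope, *A_BOUNDS))

    def model(x, k, a):
        return ROOM_AIR_PERCENT + k * x ** (-a)

    popt, _ = curve_fit(
        model,
        mv,
        fio2,
        p0=(k0, a0),
        bounds=([K_BOUNDS[0], A_BOUNDS[0]], [K_BOUNDS[1], A_BOUNDS[1]]),
        ftol=1e-10,
        xtol=1e-10,
        gtol=1e-10,
        maxfev=10000,
    )
    k, a = (float(p) for p in popt)
    r2 = r_squared(fio2, model(mv, k, a))
    return PowerFitResult(k=k, a=a, r2=r2, n_points=int(mv.size), flow_l_min=flow_l_min)


def fit_per_flow(dataset: pd.DataFrame) -> pd.DataFrame:
    """Fit the power law per cannula flow on replicate-averaged data.

    ``dataset`` follows the simulated-protocol CSV contract (columns
    mv_ml_min, flow_l_min, fio2_percent, one row per replicate).  Returns a
    frame with columns flow_l_min, k, a, r2, n_points.
    """
    cell_cols = ["vt_ml", "rr_bpm", "ti_ms"]
    rows = []
    for flow, grp in dataset.groupby("flow_l_min", sort=True):
        cells = grp.groupby(cell_cols, as_index=False).agg(
            mv_ml_min=("mv_ml_min", "first"), fio2_percent=("fio2_percent", "mean")
        )
        fit = fit_power_law(
            cells["mv_ml_min"], cells["fio2_percent"], flow_l_min=float(flow)
        )
        rows.append(
            {
                "flow_l_min": fit.flow_l_min,
                "k": fit.k,
                "a": fit.a,
                "r2": fit.r2,
                "n_points": fit.n_points,
            }
        )
    return pd.DataFrame(rows, columns=["flow_l_min", "k", "a", "r2", "n_points"])
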
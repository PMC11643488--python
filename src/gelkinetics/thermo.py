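"""Glass-transition estimation from volume-temperature series.

At the glass transition the thermal expansion (dV/dT at constant pressure)
changes abruptly, producing a break in the V(T) line.  The series is fitted
with a continuous two-segment ("hinge") linear model

    V(T) = V_b + s_low * (T - T_g)   for T <  T_g
    V(T) = V_b + s_high * (T - T_g)  for T >= T_g

by least squares: the breakpoint is located by a grid search over interior
data temperatures followed by bounded scalar refinement of the residual sum
of squares.  T_g is the intersection of the two segments.  A physical glass
transition has s_high >= s_low (larger expansion in the melt).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import GelKineticsError


@dataclass
class VTSeries:
    """Volume-temperature series; descending (cooling) order is allowed and
    sorted internally."""

    temperatures: np.ndarray  # K
    volumes: np.ndarray  # A^3
    true_break: Optional[float] = None  # ground truth when generated
    degenerate: bool = False  # generator-level single-line flag

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.temperatures.shape != self.volumes.shape or self.temperatures.ndim != 1:
            raise GelKineticsError("temperatures and volumes must be matching 1-D arrays")
        if len(self.temperatures) < 6:
            raise GelKineticsError("V(T) series needs at least 6 points")
        order = np.argsort(self.temperatures)
        self.temperatures = self.temperatures[order]
        self.volumes = self.volumes[order]
        if np.any(np.diff(self.temperatures) <= 0):
            raise GelKineticsError("temperatures must be distinct")


@dataclass
class TgFit:
    tg: float  # K
    slope_below: float  # A^3/K
    slope_above: float  # A^3/K
    v_break: float  # A^3
    sse: float
    tg_se: Optional[float]  # bootstrap s.e., None when n_boot == 0
    degenerate: bool  # slopes indistinguishable: tg unreliable
    physical: bool  # slope_above >= slope_below


def _hinge_lstsq(t: np.ndarray, v: np.ndarray, tb: float):
    """LS fit of the continuous hinge model at a fixed breakpoint."""
    A = np.column_stack([np.ones_like(t), np.minimum(t - tb, 0.0), np.maximum(t - tb, 0.0)])
    coef, _, _, _ = np.linalg.lstsq(A, v, rcond=None)
    resid = v - A @ coef
    return coef, float(resid @ resid)


def _fit_break(t: np.ndarray, v: np.ndarray, edge: int = 3):
    """Grid search over interior data temperatures + bounded refinement."""
    candidates = t[edge:-edge]
    if len(candidates) == 0:
        raise GelKineticsError(
            f"need at least 3 points on each side of a candidate breakpoint "
            f"({len(t)} points total)")
    sses = np.array([_hinge_lstsq(t, v, tb)[1] for tb in candidates])
    ibest = int(np.argmin(sses))
    lo = candidates[max(ibest - 1, 0)]
    hi = candidates[min(ibest + 1, len(candidates) - 1)]
    if hi > lo:
        res = minimize_scalar(lambda tb: _hinge_lstsq(t, v, tb)[1],
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-6})
        tb = float(res.x)
        if _hinge_lstsq(t, v, tb)[1] > sses[ibest]:
            tb = float(candidates[ibest])
    else:
        tb = float(candidates[ibest])
    return tb


def fit_bilinear(series: VTSeries, n_boot: int = 100, seed: int = 0) -> TgFit:
    """Continuous bilinear fit of V(T); T_g is the segment intersection.

    ``n_boot`` residual-bootstrap replicates give the breakpoint standard
    error (0 disables).  A series with indistinguishable slopes is returned
    flagged ``degenerate`` with an unreliable T_g.  The result is invariant
    to the input temperature ordering.
    """
    t, v = series.temperatures, series.volumes
    tb = _fit_break(t, v)
    coef, sse = _hinge_lstsq(t, v, tb)
    v_b, s_low, s_high = float(coef[0]), float(coef[1]), float(coef[2])
    scale = max(abs(s_low), abs(s_high), 1e-300)
    degenerate = abs(s_high - s_low) <= 1e-6 * scale
    tg_se = None
    if n_boot > 0 and not degenerate:
        rng = np.random.default_rng(seed)
        A = np.column_stack([np.ones_like(t), np.minimum(t - tb, 0.0), np.maximum(t - tb, 0.0)])
        fitted = A @ coef
        resid = v - fitted
        reps = []
        for _ in range(n_boot):
            vb = fitted + rng.choice(resid, size=len(resid), replace=True)
            try:
                reps.append(_fit_break(t, vb))
            except GelKineticsError:
                continue
        if len(reps) > 1:
            tg_se = float(np.std(reps, ddof=1))
    return TgFit(tg=tb, slope_below=s_low, slope_above=s_high, v_break=v_b,
                 sse=sse, tg_se=tg_se, degenerate=degenerate,
                 physical=s_high >= s_low)


def thermal_expansion(series: VTSeries, fit: TgFit):
    """Segment slopes (dV/dT below and above T_g) with standard errors.

    Returns ((slope_below, se_below), (slope_above, se_above), physical).
    """
    t, v = series.temperatures, series.volumes

    def seg_se(mask):
        ts, vs = t[mask], v[mask]
        if len(ts) < 3:
            return float("nan")
        A = np.column_stack([ts, np.ones_like(ts)])
        coef, _, _, _ = np.linalg.lstsq(A, vs, rcond=None)
        resid = vs - A @ coef
        sigma2 = float(resid @ resid) / max(len(ts) - 2, 1)
        cov = sigma2 * np.linalg.inv(A.T @ A)
        return math.sqrt(max(cov[0, 0], 0.0))

    below = (fit.slope_below, seg_se(t < fit.tg))
    above = (fit.slope_above, seg_se(t >= fit.tg))
    return below, above, fit.physical
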
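"""Time-dependent analyses: MSD, subdiffusion fitting, Einstein diffusion,
van Hove self-correlation and hopping-mode detection.

The mean square displacement over lag t is the particle- and time-origin-
averaged squared displacement

    <r^2(t)> = (1/N) sum_i |r_i(t0 + t) - r_i(t0)|^2 ,

fitted over an explicit window with the anomalous-diffusion power law
<r^2(t)> = K_alpha t^alpha.  In the linear (alpha ~ 1) regime the Einstein
relation D = slope/6 gives the diffusion coefficient.  The self-part of the
van Hove function G_s(r, t) is the probability density of displacement
magnitudes; its radial shell mass 4*pi*r^2*G_s*dr integrates to one per lag
and its second moment equals the MSD.  Multimodality of the shell mass at a
fixed lag signals cage-to-cage hopping.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import GelKineticsError
from .synthetic import CM2_PER_S_PER_A2_PER_PS
from .trajectory import Selection, Trajectory


@dataclass
class MSDCurve:
    lag_times: np.ndarray  # ps
    msd: np.ndarray  # A^2
    n_origins: np.ndarray  # origins averaged per lag
    selection: Optional[str] = None


@dataclass
class PowerLawFit:
    """<r^2(t)> = K_alpha * t^alpha fitted by least squares on log-log axes."""

    alpha: float
    k_alpha: float  # A^2 / ps^alpha
    window: tuple[float, float]  # ps
    r_squared: float
    residual_sd: float  # on log10 scale
    n_points: int


@dataclass
class DiffusionResult:
    d: float  # cm^2/s
    window: tuple[float, float]  # ps
    slope_se: float  # A^2/ps
    alpha_check: float  # power-law exponent on the same window
    nonlinear_warning: bool


@dataclass
class VanHoveSelf:
    lag_times: np.ndarray  # ps
    bin_centers: np.ndarray  # A
    gs: np.ndarray  # (n_lags, n_bins), per-A^3 density
    shell_mass: np.ndarray  # (n_lags, n_bins), 4*pi*r^2*gs*dr; rows sum to 1
    dr: float

    def row(self, lag: float) -> int:
        i = int(np.argmin(np.abs(self.lag_times - lag)))
        if not math.isclose(self.lag_times[i], lag, rel_tol=1e-9, abs_tol=1e-9):
            raise GelKineticsError(f"lag {lag} ps not present; have {self.lag_times}")
        return i

    def second_moment(self, lag: float) -> float:
        """Second moment of the displacement distribution at a lag (A^2)."""
        i = self.row(lag)
        return float(np.sum(self.shell_mass[i] * self.bin_centers ** 2))


def _lag_frames(traj: Trajectory, max_lag: Optional[float], log_spaced: bool,
                per_decade: int) -> np.ndarray:
    max_lag = traj.duration if max_lag is None else max_lag
    if max_lag <= 0 or max_lag > traj.duration + 1e-9:
        raise GelKineticsError(
            f"max_lag must be in (0, duration={traj.duration} ps], got {max_lag}")
    kmax = int(round(max_lag / traj.dt))
    if log_spaced:
        ks = np.unique(np.round(np.logspace(0, math.log10(kmax),
                                            max(int(per_decade * math.log10(kmax)) + 1, 2))
                                ).astype(int))
        ks = ks[(ks >= 1) & (ks <= kmax)]
    else:
        ks = np.arange(1, kmax + 1)
    return ks


def msd(
    traj: Trajectory,
    selection: Selection = None,
    max_lag: Optional[float] = None,
    origin_stride: int = 1,
    log_spaced: bool = True,
    per_decade: int = 20,
) -> MSDCurve:
    """Particle- and origin-averaged MSD on a (by default log-spaced) lag grid.

    The trajectory must be unwrapped.  ``origin_stride`` thins the sliding
    time origins; overlapping origins (stride 1) are the default.
    """
    if traj.wrapped:
        raise GelKineticsError("msd requires an unwrapped trajectory (see unwrap())")
    if origin_stride < 1:
        raise GelKineticsError("origin_stride must be >= 1")
    idx = traj.select(selection)
    pos = traj.positions[:, idx, :]
    ks = _lag_frames(traj, max_lag, log_spaced, per_decade)
    lags = np.concatenate([[0.0], ks * traj.dt])
    vals = [0.0]
    origins = [pos.shape[0]]
    for k in ks:
        d = pos[k::origin_stride][: (pos.shape[0] - k - 1) // origin_stride + 1] \
            - pos[:-k:origin_stride][: (pos.shape[0] - k - 1) // origin_stride + 1]
        vals.append(float(np.mean(np.sum(d * d, axis=2))))
        origins.append(d.shape[0])
    sel_name = selection if isinstance(selection, str) else None
    return MSDCurve(lag_times=lags, msd=np.asarray(vals),
                    n_origins=np.asarray(origins), selection=sel_name)


def default_window(curve: MSDCurve) -> tuple[float, float]:
    """One inner decade of the available positive lags (geometric middle)."""
    t = curve.lag_times[curve.lag_times > 0]
    mid = 0.5 * (math.log10(t.min()) + math.log10(t.max()))
    return (10 ** (mid - 0.5), 10 ** (mid + 0.5))


def fit_power_law(curve: MSDCurve, window: Optional[tuple[float, float]] = None) -> PowerLawFit:
    """Fit log <r^2> = log K_alpha + alpha log t over a lag window.

    The window defaults to one inner decade of available lags; at least 5
    lag points with strictly positive MSD are required.
    """
    if window is None:
        window = default_window(curve)
    t_min, t_max = window
    mask = (curve.lag_times >= t_min) & (curve.lag_times <= t_max) & (curve.lag_times > 0)
    if mask.sum() < 5:
        raise GelKineticsError(
            f"need >= 5 lag points in window ({t_min}, {t_max}) ps, have {int(mask.sum())}")
    t = curve.lag_times[mask]
    y = curve.msd[mask]
    if np.any(y <= 0):
        raise GelKineticsError("non-positive MSD values inside the fit window")
    lt, ly = np.log10(t), np.log10(y)
    A = np.column_stack([lt, np.ones_like(lt)])
    coef, res, *_ = np.linalg.lstsq(A, ly, rcond=None)
    alpha, intercept = float(coef[0]), float(coef[1])
    pred = A @ coef
    ss_res = float(np.sum((ly - pred) ** 2))
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    resid_sd = math.sqrt(ss_res / max(len(ly) - 2, 1))
    return PowerLawFit(alpha=alpha, k_alpha=10 ** intercept, window=(float(t_min), float(t_max)),
                       r_squared=r2, residual_sd=resid_sd, n_points=int(mask.sum()))


def diffusion_coefficient(curve: MSDCurve,
                          window: Optional[tuple[float, float]] = None) -> DiffusionResult:
    """Einstein diffusion coefficient D = slope/6 of the MSD (cm^2/s).

    The window should lie in the linear regime; if the local power-law
    exponent falls outside [0.9, 1.1] the result is flagged with
    ``nonlinear_warning`` rather than rejected.
    """
    if window is None:
        window = default_window(curve)
    t_min, t_max = window
    mask = (curve.lag_times >= t_min) & (curve.lag_times <= t_max) & (curve.lag_times > 0)
    if mask.sum() < 2:
        raise GelKineticsError(f"need >= 2 lag points in window ({t_min}, {t_max}) ps")
    t = curve.lag_times[mask]
    y = curve.msd[mask]
    A = np.column_stack([t, np.ones_like(t)])
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    slope = float(coef[0])
    if slope < 0:
        raise GelKineticsError("negative MSD slope: no meaningful diffusion coefficient")
    resid = y - A @ coef
    dof = max(len(t) - 2, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(A.T @ A)
    slope_se = math.sqrt(max(cov[0, 0], 0.0))
    try:
        alpha = fit_power_law(curve, window).alpha
    except GelKineticsError:
        alpha = float("nan")
    warn = not (0.9 <= alpha <= 1.1)
    return DiffusionResult(d=slope / 6.0 * CM2_PER_S_PER_A2_PER_PS,
                           window=(float(t_min), float(t_max)),
                           slope_se=slope_se, alpha_check=alpha, nonlinear_warning=warn)


def van_hove_self(
    traj: Trajectory,
    selection: Selection = None,
    lag_times: Sequence[float] = (10.0,),
    dr: float = 0.1,
    r_max: float = 10.0,
    origin_stride: int = 1,
) -> VanHoveSelf:
    """Self-part of the van Hove function as a radial displacement histogram.

    For each lag, displacement magnitudes over all particles and time
    origins are binned into shells of width ``dr`` up to ``r_max``.  The
    shell mass (4*pi*r^2*G_s*dr) is normalized to sum to one; displacements
    beyond ``r_max`` raise, so no probability mass is silently lost.
    """
    if traj.wrapped:
        raise GelKineticsError("van_hove_self requires an unwrapped trajectory")
    if dr <= 0 or r_max <= dr:
        raise GelKineticsError("need 0 < dr < r_max")
    idx = traj.select(selection)
    pos = traj.positions[:, idx, :]
    edges = np.arange(0.0, r_max + dr * 0.5, dr)
    centers = 0.5 * (edges[:-1] + edges[1:])
    lag_times = np.asarray(lag_times, dtype=float)
    gs_rows, mass_rows = [], []
    for lag in lag_times:
        k = int(round(lag / traj.dt))
        if k < 1 or k >= pos.shape[0] or not math.isclose(k * traj.dt, lag, rel_tol=1e-6):
            raise GelKineticsError(
                f"lag {lag} ps is not a positive multiple of dt={traj.dt} ps within duration")
        d = pos[k::origin_stride][: (pos.shape[0] - k - 1) // origin_stride + 1] \
            - pos[:-k:origin_stride][: (pos.shape[0] - k - 1) // origin_stride + 1]
        r = np.sqrt(np.sum(d * d, axis=2)).ravel()
        if r.max() >= r_max:
            raise GelKineticsError(
                f"displacement {r.max():.3f} A exceeds r_max={r_max} A at lag {lag} ps; "
                "increase r_max to conserve probability")
        hist, _ = np.histogram(r, bins=edges)
        mass = hist / hist.sum()
        gs_rows.append(mass / (4.0 * math.pi * centers ** 2 * dr))
        mass_rows.append(mass)
    return VanHoveSelf(lag_times=lag_times, bin_centers=centers,
                       gs=np.asarray(gs_rows), shell_mass=np.asarray(mass_rows), dr=dr)


def detect_modes(
    vh: VanHoveSelf,
    lag: float,
    smooth_width: int = 3,
    min_prominence: float = 0.05,
) -> np.ndarray:
    """Mode radii (A) of the radial shell mass 4*pi*r^2*G_s at one lag.

    The shell mass is smoothed with a moving average of ``smooth_width``
    bins; local maxima with prominence >= ``min_prominence`` times the
    smoothed maximum are reported, ordered by radius.  One mode means
    Gaussian-like motion; two or more signal hopping between cages.
    """
    i = vh.row(lag)
    y = vh.shell_mass[i].astype(float)
    if smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        y = np.convolve(y, kernel, mode="same")
    padded = np.concatenate([[0.0], y, [0.0]])  # admit boundary maxima
    peaks, _ = find_peaks(padded, prominence=min_prominence * padded.max())
    return vh.bin_centers[peaks - 1]
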
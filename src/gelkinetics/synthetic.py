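"""Synthetic trajectories and configurations with known ground truth.

These generators emulate the statistical structure of hydrogel MD output so
that every analysis stage can be validated against a known answer:

* free Brownian walkers (MSD exponent alpha = 1, diffusion D known),
* fractional Brownian motion (alpha = 2H, exact covariance synthesis),
* continuous-time random walks with heavy-tailed waiting times
  (alpha = waiting exponent mu < 1),
* cage-hopping dynamics (bimodal displacement distributions, jump-diffusion
  long-time limit),
* ideal Rouse bead-spring chains (middle-monomer alpha ~ 0.5 at
  intermediate times),
* random and lattice packings plus explicit hydrogen-bond geometries for
  the static analyses,
* bilinear volume-temperature series with a known glass-transition
  breakpoint.

Internal units are Angstrom and ps; diffusion coefficients are accepted in
cm^2/s (1 A^2/ps = 1e-4 cm^2/s).  Every generator is deterministic under a
fixed seed.  Trajectories are emitted unwrapped; use
:func:`gelkinetics.trajectory.wrap` for wrapped variants.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import GelKineticsError
from .trajectory import Configuration, Trajectory

#: cm^2/s per A^2/ps
CM2_PER_S_PER_A2_PER_PS = 1e-4


def diffusion_to_a2ps(d_cm2_s: float) -> float:
    return d_cm2_s / CM2_PER_S_PER_A2_PER_PS


@dataclass
class WalkerParams:
    """Parameters for the point-walker generators.

    Only the fields relevant to ``model`` are used: ``diffusion`` (cm^2/s)
    for Brownian; ``hurst`` for fractional Brownian motion; ``waiting_exponent``
    and ``jump_length`` for the CTRW; ``jump_length``, ``hop_rate`` (1/ps),
    ``cage_sigma`` and ``cage_tau`` for the cage hopper.
    """

    model: str = "brownian"
    n_particles: int = 100
    n_steps: int = 1000
    dt: float = 1.0  # ps
    diffusion: float = 1e-5  # cm^2/s
    hurst: float = 0.5
    waiting_exponent: float = 0.7
    jump_length: float = 1.0  # A
    hop_rate: float = 0.0  # 1/ps
    cage_sigma: float = 0.3  # A
    cage_tau: Optional[float] = None  # ps, in-cage relaxation; default dt
    seed: int = 0

    def validate_common(self):
        if self.n_particles < 1 or self.n_steps < 1:
            raise GelKineticsError("n_particles and n_steps must be >= 1")
        if self.dt <= 0:
            raise GelKineticsError("dt must be positive")


def _walker_labels(n: int) -> np.ndarray:
    return np.asarray([f"w{i:04d}" for i in range(n)], dtype=object)


def _as_trajectory(pos: np.ndarray, dt: float) -> Trajectory:
    return Trajectory(positions=pos, dt=dt, labels=_walker_labels(pos.shape[1]), wrapped=False)


def gen_brownian(params: WalkerParams) -> Trajectory:
    """Free 3-D Brownian walkers: i.i.d. Gaussian increments with per-axis
    variance 2*D*dt.  ``D = 0`` produces static particles."""
    params.validate_common()
    if params.model != "brownian":
        raise GelKineticsError(f"model must be 'brownian', got {params.model!r}")
    if params.diffusion < 0:
        raise GelKineticsError("diffusion must be >= 0")
    rng = np.random.default_rng(params.seed)
    a = diffusion_to_a2ps(params.diffusion)
    sd = math.sqrt(2.0 * a * params.dt)
    inc = rng.normal(0.0, sd, size=(params.n_steps, params.n_particles, 3)) if sd > 0 else \
        np.zeros((params.n_steps, params.n_particles, 3))
    pos = np.concatenate([np.zeros((1, params.n_particles, 3)), np.cumsum(inc, axis=0)])
    return _as_trajectory(pos, params.dt)


def _fgn_davies_harte(n: int, hurst: float, rng: np.random.Generator, n_series: int) -> np.ndarray:
    """Exact fractional Gaussian noise (unit variance per step) by circulant
    embedding of the fGn autocovariance; returns (n_series, n)."""
    k = np.arange(n + 1)
    gamma = 0.5 * (np.abs(k + 1) ** (2 * hurst) - 2 * np.abs(k) ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    c = np.concatenate([gamma[:-1], gamma[::-1][:-1]])  # length 2n
    lam = np.fft.fft(c).real
    lam = np.maximum(lam, 0.0)  # clip tiny negative round-off
    m = 2 * n
    # Hermitian-symmetric complex Gaussian spectrum
    z = np.empty((n_series, m), dtype=complex)
    z[:, 0] = rng.normal(size=n_series) * np.sqrt(lam[0])
    z[:, n] = rng.normal(size=n_series) * np.sqrt(lam[n])
    half = rng.normal(size=(n_series, n - 1)) + 1j * rng.normal(size=(n_series, n - 1))
    z[:, 1:n] = half * np.sqrt(lam[1:n] / 2.0)
    z[:, n + 1:] = np.conj(z[:, 1:n][:, ::-1])
    x = np.fft.fft(z, axis=1).real / math.sqrt(m)
    return x[:, :n]


def fgn_autocovariance(hurst: float, lags: np.ndarray) -> np.ndarray:
    """Closed-form autocovariance of unit-variance fractional Gaussian noise."""
    k = np.abs(np.asarray(lags, dtype=float))
    return 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))


def gen_fbm(params: WalkerParams) -> Trajectory:
    """Fractional Brownian walkers; each axis is an exact fBM path.

    Ground-truth MSD exponent is alpha = 2*hurst; the per-axis MSD is
    ``jump_length^2 * (t/dt)^(2H)``.
    """
    params.validate_common()
    if params.model != "fbm":
        raise GelKineticsError(f"model must be 'fbm', got {params.model!r}")
    if not 0.0 < params.hurst < 1.0:
        raise GelKineticsError(f"hurst must be strictly inside (0, 1), got {params.hurst}")
    rng = np.random.default_rng(params.seed)
    n, npart = params.n_steps, params.n_particles
    inc = _fgn_davies_harte(n, params.hurst, rng, npart * 3).reshape(npart, 3, n)
    inc = np.moveaxis(inc, 2, 0) * params.jump_length  # (n_steps, npart, 3)
    pos = np.concatenate([np.zeros((1, npart, 3)), np.cumsum(inc, axis=0)])
    return _as_trajectory(pos, params.dt)


def gen_ctrw(params: WalkerParams) -> Trajectory:
    """Continuous-time random walk: Pareto waiting times with exponent
    mu = ``waiting_exponent`` in (0,1) (minimum wait dt), isotropic Gaussian
    jumps of per-axis s.d. ``jump_length``.  Ensemble MSD grows as t^mu."""
    params.validate_common()
    if params.model != "ctrw":
        raise GelKineticsError(f"model must be 'ctrw', got {params.model!r}")
    mu = params.waiting_exponent
    if not 0.0 < mu < 1.0:
        raise GelKineticsError(
            f"waiting_exponent must be in (0, 1); got {mu} (mu >= 1 is the "
            "normal-diffusion regime, use the brownian generator)")
    if params.jump_length < 0:
        raise GelKineticsError("jump_length must be >= 0")
    rng = np.random.default_rng(params.seed)
    total = params.n_steps * params.dt
    grid = np.arange(params.n_steps + 1) * params.dt
    pos = np.zeros((params.n_steps + 1, params.n_particles, 3))
    for i in range(params.n_particles):
        waits = []
        t_acc = 0.0
        while t_acc <= total:
            chunk = params.dt * rng.random(256) ** (-1.0 / mu)
            waits.append(chunk)
            t_acc += chunk.sum()
        event_times = np.cumsum(np.concatenate(waits))
        event_times = event_times[event_times <= total]
        jumps = rng.normal(0.0, params.jump_length, size=(len(event_times), 3))
        walk = np.concatenate([np.zeros((1, 3)), np.cumsum(jumps, axis=0)])
        n_events = np.searchsorted(event_times, grid, side="right")
        pos[:, i, :] = walk[n_events]
    return _as_trajectory(pos, params.dt)


def gen_cage_hopper(params: WalkerParams) -> Trajectory:
    """Cage rattling punctuated by discrete hops.

    Position = cage center + Ornstein-Uhlenbeck fluctuation of stationary
    s.d. ``cage_sigma`` (relaxation time ``cage_tau``, default dt).  The cage
    center jumps a fixed distance ``jump_length`` in a random direction at
    Poisson times with rate ``hop_rate``; long-time MSD slope is
    ``hop_rate * jump_length^2``.
    """
    params.validate_common()
    if params.model != "cage_hop":
        raise GelKineticsError(f"model must be 'cage_hop', got {params.model!r}")
    if params.hop_rate < 0 or params.cage_sigma < 0 or params.jump_length < 0:
        raise GelKineticsError("hop_rate, cage_sigma and jump_length must be >= 0")
    if params.hop_rate * params.dt > 0.5:
        raise GelKineticsError(
            f"hop_rate*dt = {params.hop_rate * params.dt:.3f} > 0.5: time "
            "resolution too coarse to resolve individual hops")
    rng = np.random.default_rng(params.seed)
    nsteps, npart = params.n_steps, params.n_particles
    tau = params.cage_tau if params.cage_tau is not None else params.dt
    rho = math.exp(-params.dt / tau) if tau > 0 else 0.0
    # cage-center jump process
    hops = rng.random((nsteps, npart)) < params.hop_rate * params.dt
    direc = rng.normal(size=(nsteps, npart, 3))
    direc /= np.linalg.norm(direc, axis=2, keepdims=True)
    jumps = direc * params.jump_length * hops[..., None]
    centers = np.concatenate([np.zeros((1, npart, 3)), np.cumsum(jumps, axis=0)])
    # stationary OU fluctuation about the center
    fluct = np.empty((nsteps + 1, npart, 3))
    fluct[0] = rng.normal(0.0, params.cage_sigma or 0.0, size=(npart, 3))
    innov_sd = params.cage_sigma * math.sqrt(max(1.0 - rho * rho, 0.0))
    for k in range(1, nsteps + 1):
        fluct[k] = rho * fluct[k - 1] + rng.normal(0.0, innov_sd or 0.0, size=(npart, 3))
    return _as_trajectory(centers + fluct, params.dt)


@dataclass
class RouseParams:
    """Ideal (phantom) harmonic bead-spring chain in reduced units
    (k_B T = 1).  Stability requires dt*spring_constant/friction < 0.25."""

    n_beads: int = 64
    spring_constant: float = 1.0
    friction: float = 1.0
    dt: float = 0.05
    n_steps: int = 2000
    n_chains: int = 1
    seed: int = 0

    def validate(self):
        if self.n_beads < 1:
            raise GelKineticsError("n_beads must be >= 1")
        if self.n_beads > 1 and self.n_beads < 8:
            raise GelKineticsError("chains need n_beads >= 8 (or exactly 1 for a free bead)")
        if self.spring_constant <= 0 or self.friction <= 0 or self.dt <= 0:
            raise GelKineticsError("spring_constant, friction and dt must be positive")
        if self.n_beads > 1 and self.dt * self.spring_constant / self.friction >= 0.25:
            raise GelKineticsError(
                f"unstable integration: dt*k/zeta = "
                f"{self.dt * self.spring_constant / self.friction:.3f} >= 0.25")


def middle_bead_label(params: RouseParams) -> str:
    return f"b{params.n_beads // 2}"


def gen_rouse(params: RouseParams) -> Trajectory:
    """Overdamped Langevin integration of ideal Rouse chains.

    Chains start from the exact equilibrium distribution (i.i.d. Gaussian
    bond vectors), so time-origin averaging is stationary from frame 0.
    Beads are labelled ``b0..b{N-1}`` within each chain;
    :func:`middle_bead_label` gives the selection label for the middle
    monomer, whose intermediate-time MSD exponent is ~0.5.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    N, C = params.n_beads, params.n_chains
    k, zeta, dt = params.spring_constant, params.friction, params.dt
    bond_sd = 1.0 / math.sqrt(k)  # k_B T = 1
    bonds = rng.normal(0.0, bond_sd, size=(C, max(N - 1, 0), 3))
    x = np.concatenate([np.zeros((C, 1, 3)), np.cumsum(bonds, axis=1)], axis=1)
    noise_sd = math.sqrt(2.0 * dt / zeta)
    pos = np.empty((params.n_steps + 1, C * N, 3))
    pos[0] = x.reshape(C * N, 3)
    coef = dt * k / zeta
    for s in range(1, params.n_steps + 1):
        if N > 1:
            force = np.empty_like(x)
            force[:, 0] = x[:, 1] - x[:, 0]
            force[:, -1] = x[:, -2] - x[:, -1]
            force[:, 1:-1] = x[:, :-2] + x[:, 2:] - 2.0 * x[:, 1:-1]
            x = x + coef * force + rng.normal(0.0, noise_sd, size=x.shape)
        else:
            x = x + rng.normal(0.0, noise_sd, size=x.shape)
        pos[s] = x.reshape(C * N, 3)
    labels = np.asarray([f"b{b}" for _ in range(C) for b in range(N)], dtype=object)
    return Trajectory(positions=pos, dt=dt, labels=labels, wrapped=False)


# ---------------------------------------------------------------------------
# static configurations

def gen_packing(kind: str, n: int, box: float, spacing: float = 1.0, seed: int = 0) -> Configuration:
    """Labelled point packing in a cubic periodic box.

    ``lattice``: simple cubic grid (n must be a perfect cube and the grid
    must fit the box).  ``poisson``: uniform random points.
    """
    if n < 1 or box <= 0:
        raise GelKineticsError("n must be >= 1 and box positive")
    rng = np.random.default_rng(seed)
    if kind == "lattice":
        m = round(n ** (1.0 / 3.0))
        if m ** 3 != n:
            raise GelKineticsError(f"lattice packing needs a perfect-cube count, got {n}")
        if spacing <= 0:
            raise GelKineticsError("spacing must be positive")
        if m * spacing > box * (1 + 1e-12):
            raise GelKineticsError(
                f"overfilled box: {m} sites of spacing {spacing} need {m*spacing} A > box {box} A")
        axes = np.arange(m) * spacing
        gx, gy, gz = np.meshgrid(axes, axes, axes, indexing="ij")
        pos = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    elif kind == "poisson":
        pos = rng.random((n, 3)) * box
    else:
        raise GelKineticsError(f"unknown packing kind {kind!r}")
    labels = np.asarray(["site"] * n, dtype=object)
    return Configuration(positions=pos, box_edge=box, labels=labels)


def gen_hbond_fixture(
    geometries: Sequence[tuple[float, float, float]],
    box_edge: Optional[float] = None,
    donor_label: str = "O_W",
    hydrogen_label: str = "H_W",
    acceptor_label: str = "O_H1",
) -> Configuration:
    """Explicit donor/hydrogen/acceptor triples realizing requested geometries.

    Each geometry is (d_DA, d_HA, angle_dev) with the deviation of the
    D-H...A angle from linearity in degrees.  The covalent D-H distance is
    determined by the triangle (law of cosines); geometries whose implied
    D-H distance is non-positive or imaginary raise.  Triples are spaced far
    apart so no cross-triple bonds occur.
    """
    positions, labels, elements, roles = [], [], [], []
    pitch = 15.0
    for i, (d_da, d_ha, dev) in enumerate(geometries):
        if d_da <= 0 or d_ha <= 0 or dev < 0 or dev >= 180:
            raise GelKineticsError(f"geometry {i}: invalid (d_DA, d_HA, angle_dev) = "
                                   f"({d_da}, {d_ha}, {dev})")
        theta = math.radians(180.0 - dev)  # D-H...A angle at the hydrogen
        disc = d_da * d_da - (d_ha * math.sin(theta)) ** 2
        if disc < 0:
            raise GelKineticsError(f"geometry {i}: unrealizable triple "
                                   f"(d_DA={d_da}, d_HA={d_ha}, dev={dev})")
        d_dh = d_ha * math.cos(theta) + math.sqrt(disc)
        if d_dh <= 0:
            raise GelKineticsError(
                f"geometry {i}: unrealizable triple (implied D-H distance non-positive)")
        base = np.array([pitch * (i + 0.5), pitch * 0.5, pitch * 0.5])
        d_pos = base
        h_pos = base + np.array([d_dh, 0.0, 0.0])
        phi = math.radians(dev)
        a_pos = h_pos + d_ha * np.array([math.cos(phi), math.sin(phi), 0.0])
        positions.extend([d_pos, h_pos, a_pos])
        labels.extend([donor_label, hydrogen_label, acceptor_label])
        elements.extend(["O", "H", "O"])
        roles.extend(["donor", "hydrogen", "acceptor"])
    n = len(positions)
    box = box_edge if box_edge is not None else max(pitch * max(len(geometries), 1), pitch)
    return Configuration(
        positions=np.asarray(positions).reshape(n, 3),
        box_edge=box,
        labels=np.asarray(labels, dtype=object),
        elements=np.asarray(elements, dtype=object),
        hbond_roles=np.asarray(roles, dtype=object),
    )


# ---------------------------------------------------------------------------
# volume-temperature series

@dataclass
class BilinearVTParams:
    """Two-segment linear volume-temperature series with a known breakpoint.

    Emulates a cooling protocol for glass-transition fitting: the default
    grid runs 650 K down to 200 K in 25 K steps; ``slope_high`` applies
    above the break (melt), ``slope_low`` below (glass).
    """

    t_break: float = 425.0  # K
    slope_low: float = 0.5  # A^3/K
    slope_high: float = 1.2  # A^3/K
    v_break: float = 10000.0  # A^3
    noise_sd: float = 0.0  # A^3
    t_grid: Optional[np.ndarray] = None  # K
    seed: int = 0

    def grid(self) -> np.ndarray:
        if self.t_grid is None:
            return np.arange(650.0, 199.0, -25.0)
        return np.asarray(self.t_grid, dtype=float)


def gen_bilinear_vt(params: BilinearVTParams):
    """Generate a VTSeries from a continuous bilinear model plus noise."""
    from .thermo import VTSeries

    t = params.grid()
    if len(t) < 6:
        raise GelKineticsError("temperature grid needs at least 6 points")
    if not (t.min() < params.t_break < t.max()):
        raise GelKineticsError(
            f"t_break={params.t_break} K lies outside the grid [{t.min()}, {t.max()}] K")
    if params.slope_low < 0 or params.slope_high < 0:
        raise GelKineticsError("slopes must be non-negative")
    degenerate = math.isclose(params.slope_low, params.slope_high, rel_tol=1e-12, abs_tol=1e-12)
    dtb = t - params.t_break
    v = params.v_break + np.where(dtb < 0, params.slope_low * dtb, params.slope_high * dtb)
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        v = v + rng.normal(0.0, params.noise_sd, size=v.shape)
    return VTSeries(temperatures=t, volumes=v,
                    true_break=params.t_break, degenerate=degenerate)
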
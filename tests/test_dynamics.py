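"""MSD, power-law fitting, Einstein diffusion, van Hove and mode detection."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gelkinetics.dynamics import (MSDCurve, detect_modes, diffusion_coefficient,
                                  fit_power_law, msd, van_hove_self)
from gelkinetics.errors import GelKineticsError
from gelkinetics.synthetic import WalkerParams, gen_brownian, gen_cage_hopper, gen_fbm
from gelkinetics.trajectory import Trajectory, wrap


def exact_curve(k_alpha, alpha, t):
    t = np.asarray(t, dtype=float)
    return MSDCurve(lag_times=t, msd=k_alpha * t ** alpha,
                    n_origins=np.zeros(len(t), dtype=int))


class TestMSD:
    def test_static_particles_zero(self):
        traj = Trajectory(positions=np.zeros((50, 4, 3)), dt=1.0)
        curve = msd(traj, max_lag=20.0)
        assert np.all(curve.msd == 0.0)
        assert curve.msd[0] == 0.0 and curve.lag_times[0] == 0.0

    def test_ballistic_closed_form(self):
        v = 0.7
        t = np.arange(100) * 0.5
        pos = np.zeros((100, 1, 3))
        pos[:, 0, 0] = v * t
        traj = Trajectory(positions=pos, dt=0.5)
        curve = msd(traj, max_lag=20.0, log_spaced=False)
        assert np.allclose(curve.msd, v ** 2 * curve.lag_times ** 2, rtol=1e-12)

    def test_wrapped_input_rejected(self):
        traj = Trajectory(positions=np.random.default_rng(0).random((10, 3, 3)),
                          dt=1.0, box_edge=1.0, wrapped=True)
        with pytest.raises(GelKineticsError, match="unwrapped"):
            msd(traj)

    def test_overlapping_vs_independent_origins_consistent(self):
        p = WalkerParams(model="brownian", n_particles=400, n_steps=600,
                         diffusion=1e-5, seed=20)
        traj = gen_brownian(p)
        lag_frames = 50
        overlapping = msd(traj, max_lag=50.0, log_spaced=False)
        i = -1  # exact 50 ps lag
        pos = traj.positions
        # overlapping estimator, per particle (particles are independent)
        d_all = pos[lag_frames:] - pos[:-lag_frames]
        per_particle_overlap = np.sum(d_all * d_all, axis=2).mean(axis=0)
        se_o = per_particle_overlap.std() / math.sqrt(len(per_particle_overlap))
        # independent origins: disjoint windows
        d = pos[lag_frames::lag_frames] - pos[:-lag_frames:lag_frames]
        per_particle_indep = np.sum(d * d, axis=2).mean(axis=0)
        se_i = per_particle_indep.std() / math.sqrt(len(per_particle_indep))
        se_diff = math.sqrt(se_o ** 2 + se_i ** 2)
        assert abs(overlapping.msd[i] - per_particle_indep.mean()) < 2 * se_diff


class TestPowerLawFit:
    def test_exact_power_law_recovered_to_machine_precision(self):
        curve = exact_curve(2.5, 0.7, np.logspace(0, 2, 40))
        fit = fit_power_law(curve, (1.0, 100.0))
        assert fit.alpha == pytest.approx(0.7, abs=1e-12)
        assert fit.k_alpha == pytest.approx(2.5, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(alpha=st.floats(0.1, 1.9), k=st.floats(0.01, 100.0))
    def test_exact_recovery_property(self, alpha, k):
        curve = exact_curve(k, alpha, np.logspace(-0.5, 2, 30))
        fit = fit_power_law(curve)
        assert fit.alpha == pytest.approx(alpha, abs=1e-9)
        assert fit.k_alpha == pytest.approx(k, rel=1e-9)

    def test_brownian_exponent_is_one(self):
        p = WalkerParams(model="brownian", n_particles=500, n_steps=2000,
                         diffusion=1e-5, seed=21)
        curve = msd(gen_brownian(p), max_lag=500.0)
        fit = fit_power_law(curve, (10.0, 100.0))
        assert fit.alpha == pytest.approx(1.0, abs=0.05)

    def test_too_few_points_rejected(self):
        curve = exact_curve(1.0, 1.0, [1, 2, 3, 100.0])
        with pytest.raises(GelKineticsError, match=">= 5 lag points"):
            fit_power_law(curve, (0.5, 5.0))

    def test_nonpositive_msd_rejected(self):
        curve = MSDCurve(lag_times=np.arange(1.0, 10.0),
                         msd=np.zeros(9), n_origins=np.zeros(9, dtype=int))
        with pytest.raises(GelKineticsError, match="non-positive"):
            fit_power_law(curve, (1.0, 9.0))

    @pytest.mark.parametrize("alpha_true,hurst", [(0.3, 0.15), (0.5, 0.25), (0.7, 0.35)])
    def test_fbm_exponent_recovery(self, alpha_true, hurst):
        errs = []
        for seed in range(3):
            p = WalkerParams(model="fbm", n_particles=500, n_steps=1024,
                             hurst=hurst, seed=30 + seed)
            curve = msd(gen_fbm(p), max_lag=1000.0)
            errs.append(fit_power_law(curve, (5.0, 500.0)).alpha - alpha_true)
        assert max(abs(e) for e in errs) <= 0.05


class TestDiffusion:
    def test_exact_linear_curve(self):
        # msd = 6 D t with D = 1e-5 cm^2/s = 0.1 A^2/ps
        curve = exact_curve(0.6, 1.0, np.linspace(1, 100, 50))
        res = diffusion_coefficient(curve, (1.0, 100.0))
        assert res.d == pytest.approx(1e-5, rel=1e-12)
        assert not res.nonlinear_warning

    def test_brownian_recovery_within_5_percent(self):
        d_true = 1.5e-5
        p = WalkerParams(model="brownian", n_particles=500, n_steps=2000,
                         diffusion=d_true, seed=22)
        curve = msd(gen_brownian(p), max_lag=500.0)
        res = diffusion_coefficient(curve, (10.0, 100.0))
        assert res.d == pytest.approx(d_true, rel=0.05)

    def test_subdiffusive_curve_flagged(self):
        curve = exact_curve(1.0, 0.7, np.logspace(0, 2, 40))
        res = diffusion_coefficient(curve, (1.0, 100.0))
        assert res.nonlinear_warning

    def test_negative_slope_rejected(self):
        t = np.linspace(1, 10, 10)
        curve = MSDCurve(lag_times=t, msd=10.0 - t,
                         n_origins=np.zeros(10, dtype=int))
        with pytest.raises(GelKineticsError, match="negative"):
            diffusion_coefficient(curve, (1.0, 10.0))


class TestVanHove:
    def test_static_particles_all_mass_in_first_bin(self):
        traj = Trajectory(positions=np.zeros((30, 5, 3)), dt=1.0)
        vh = van_hove_self(traj, lag_times=[5.0], dr=0.1, r_max=2.0)
        assert vh.shell_mass[0, 0] == pytest.approx(1.0)
        assert np.all(vh.shell_mass[0, 1:] == 0.0)
        assert detect_modes(vh, 5.0)[0] == vh.bin_centers[0]

    def test_shell_mass_normalized(self):
        p = WalkerParams(model="brownian", n_particles=200, n_steps=300,
                         diffusion=1e-5, seed=23)
        vh = van_hove_self(gen_brownian(p), lag_times=[5.0, 20.0], dr=0.1, r_max=25.0)
        assert np.allclose(vh.shell_mass.sum(axis=1), 1.0, atol=1e-6)

    def test_brownian_matches_gaussian_propagator(self):
        d_a2ps = 0.1  # 1e-5 cm^2/s
        lag = 10.0
        p = WalkerParams(model="brownian", n_particles=500, n_steps=1000,
                         diffusion=1e-5, seed=24)
        vh = van_hove_self(gen_brownian(p), lag_times=[lag], dr=0.1, r_max=25.0)
        r = vh.bin_centers
        gauss = (4 * math.pi * d_a2ps * lag) ** (-1.5) * np.exp(-r ** 2 / (4 * d_a2ps * lag))
        # compare where the propagator carries real mass
        mask = gauss > gauss.max() * 1e-3
        n_samples = 500 * (1000 - int(lag))
        expected_mass = 4 * math.pi * r ** 2 * gauss * vh.dr
        se = np.sqrt(np.maximum(expected_mass * (1 - expected_mass), 1e-12) / n_samples)
        # correlated origins inflate the variance; allow a generous factor
        assert np.all(np.abs(vh.shell_mass[0, mask] - expected_mass[mask]) < 30 * se[mask])

    def test_second_moment_equals_msd(self):
        p = WalkerParams(model="brownian", n_particles=300, n_steps=500,
                         diffusion=1e-5, seed=25)
        traj = gen_brownian(p)
        lag = 10.0
        vh = van_hove_self(traj, lag_times=[lag], dr=0.05, r_max=25.0)
        curve = msd(traj, max_lag=50.0, log_spaced=False)
        i = np.argmin(np.abs(curve.lag_times - lag))
        assert vh.second_moment(lag) == pytest.approx(curve.msd[i], rel=0.01)

    def test_rmax_overflow_rejected(self):
        p = WalkerParams(model="brownian", n_particles=50, n_steps=200,
                         diffusion=1e-5, seed=26)
        with pytest.raises(GelKineticsError, match="r_max"):
            van_hove_self(gen_brownian(p), lag_times=[50.0], dr=0.1, r_max=3.0)


class TestModes:
    def test_gaussian_data_single_mode(self):
        p = WalkerParams(model="brownian", n_particles=500, n_steps=500,
                         diffusion=1e-5, seed=27)
        vh = van_hove_self(gen_brownian(p), lag_times=[10.0], dr=0.1, r_max=20.0)
        assert len(detect_modes(vh, 10.0)) == 1

    def test_hopping_gives_two_modes_then_one_at_high_rate(self):
        # mode count drops from 2 to 1 as hopping becomes fast relative to
        # the observation lag (hopping washed out, diffusion dominates)
        lag = 10.0
        counts = {}
        for rate in (0.07, 0.45):
            p = WalkerParams(model="cage_hop", n_particles=400, n_steps=1500,
                             dt=1.0, hop_rate=rate, cage_sigma=0.3,
                             jump_length=3.0, seed=28)
            vh = van_hove_self(gen_cage_hopper(p), lag_times=[lag], dr=0.25, r_max=60.0)
            counts[rate] = len(detect_modes(vh, lag))
        assert counts[0.07] == 2
        assert counts[0.45] == 1

    def test_missing_lag_rejected(self):
        p = WalkerParams(model="brownian", n_particles=20, n_steps=100,
                         diffusion=1e-5, seed=29)
        vh = van_hove_self(gen_brownian(p), lag_times=[10.0], dr=0.1, r_max=20.0)
        with pytest.raises(GelKineticsError, match="not present"):
            detect_modes(vh, 11.0)
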
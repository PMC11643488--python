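"""Ground-truth properties of the synthetic generators."""
import math

import numpy as np
import pytest

from gelkinetics.dynamics import detect_modes, fit_power_law, msd, van_hove_self
from gelkinetics.errors import GelKineticsError
from gelkinetics.synthetic import (BilinearVTParams, RouseParams, WalkerParams,
                                   fgn_autocovariance, gen_bilinear_vt,
                                   gen_brownian, gen_cage_hopper, gen_ctrw,
                                   gen_fbm, gen_hbond_fixture, gen_packing,
                                   gen_rouse, middle_bead_label)
from gelkinetics.structure import rdf


class TestBrownian:
    def test_zero_diffusion_is_static(self):
        traj = gen_brownian(WalkerParams(model="brownian", n_particles=3,
                                         n_steps=50, diffusion=0.0, seed=1))
        assert np.all(traj.positions == traj.positions[0])

    def test_increment_variance_matches_2Ddt(self):
        d_cm2 = 1e-5  # -> 0.1 A^2/ps
        p = WalkerParams(model="brownian", n_particles=300, n_steps=400,
                         dt=2.0, diffusion=d_cm2, seed=2)
        traj = gen_brownian(p)
        inc = np.diff(traj.positions, axis=0)
        target = 2 * 0.1 * p.dt
        var = inc.var()
        se = target * math.sqrt(2.0 / inc.size)
        assert abs(var - target) < 3 * se

    def test_negative_diffusion_rejected(self):
        with pytest.raises(GelKineticsError):
            gen_brownian(WalkerParams(model="brownian", diffusion=-1e-6))

    def test_deterministic_under_seed(self):
        p = WalkerParams(model="brownian", n_particles=5, n_steps=20, seed=9)
        assert np.array_equal(gen_brownian(p).positions, gen_brownian(p).positions)


class TestFBM:
    def test_increment_autocovariance_closed_form(self):
        hurst = 0.35
        p = WalkerParams(model="fbm", n_particles=200, n_steps=512,
                         hurst=hurst, seed=3)
        traj = gen_fbm(p)
        inc = np.diff(traj.positions, axis=0)  # (steps, particles, 3)
        x = np.moveaxis(inc, 0, 2).reshape(-1, inc.shape[0])
        for lag in (1, 2, 5, 10):
            prod = x[:, :-lag] * x[:, lag:]
            emp = prod.mean()
            th = fgn_autocovariance(hurst, [lag])[0]
            se = prod.std() / math.sqrt(prod.size)
            assert abs(emp - th) < 3 * se, f"lag {lag}"

    def test_alpha_is_twice_hurst(self):
        p = WalkerParams(model="fbm", n_particles=500, n_steps=2000,
                         hurst=0.35, seed=4)
        curve = msd(gen_fbm(p), max_lag=1000.0)
        fit = fit_power_law(curve, (5.0, 500.0))
        assert fit.alpha == pytest.approx(0.70, abs=0.05)

    def test_half_hurst_variance_matches_brownian_scaling(self):
        # H = 0.5 reduces to independent Gaussian increments
        p = WalkerParams(model="fbm", n_particles=300, n_steps=256,
                         hurst=0.5, seed=5)
        inc = np.diff(gen_fbm(p).positions, axis=0)
        x = np.moveaxis(inc, 0, 2).reshape(-1, inc.shape[0])
        lag1 = (x[:, :-1] * x[:, 1:]).mean()
        se = (x[:, :-1] * x[:, 1:]).std() / math.sqrt(x[:, 1:].size)
        assert abs(lag1) < 3 * se  # uncorrelated increments

    @pytest.mark.parametrize("hurst", [0.0, 1.0, -0.3, 1.2])
    def test_hurst_bounds_enforced(self, hurst):
        with pytest.raises(GelKineticsError):
            gen_fbm(WalkerParams(model="fbm", hurst=hurst))


class TestCTRW:
    def test_zero_jump_length_means_no_motion(self):
        p = WalkerParams(model="ctrw", n_particles=5, n_steps=100,
                         jump_length=0.0, waiting_exponent=0.6, seed=6)
        traj = gen_ctrw(p)
        assert np.allclose(traj.positions, 0.0)

    def test_waiting_exponent_sets_msd_scaling(self):
        p = WalkerParams(model="ctrw", n_particles=1000, n_steps=2000,
                         waiting_exponent=0.7, jump_length=1.0, seed=7)
        # ensemble (fixed-origin) MSD: the process ages, so sliding origins
        # would bias the exponent toward 1
        curve = msd(gen_ctrw(p), max_lag=2000.0, origin_stride=10 ** 9)
        fit = fit_power_law(curve, (20.0, 2000.0))
        assert 0.6 <= fit.alpha <= 0.8

    def test_normal_diffusion_regime_rejected(self):
        with pytest.raises(GelKineticsError, match="waiting_exponent"):
            gen_ctrw(WalkerParams(model="ctrw", waiting_exponent=1.0))

    def test_deterministic_under_seed(self):
        p = WalkerParams(model="ctrw", n_particles=8, n_steps=64, seed=8)
        assert np.array_equal(gen_ctrw(p).positions, gen_ctrw(p).positions)


class TestCageHopper:
    def test_no_hops_is_unimodal_cage_rattle(self):
        p = WalkerParams(model="cage_hop", n_particles=300, n_steps=500,
                         hop_rate=0.0, cage_sigma=0.3, jump_length=3.0, seed=9)
        traj = gen_cage_hopper(p)
        vh = van_hove_self(traj, lag_times=[10.0], dr=0.1, r_max=6.0)
        assert len(detect_modes(vh, 10.0)) == 1

    def test_second_mode_at_jump_length(self):
        p = WalkerParams(model="cage_hop", n_particles=500, n_steps=2000,
                         hop_rate=0.07, cage_sigma=0.3, jump_length=3.0, seed=10)
        vh = van_hove_self(gen_cage_hopper(p), lag_times=[10.0], dr=0.2, r_max=40.0)
        modes = detect_modes(vh, 10.0)
        assert len(modes) == 2
        assert abs(modes[1] - 3.0) <= 0.5

    def test_long_time_msd_is_jump_diffusion(self):
        rate, ell = 0.05, 3.0
        p = WalkerParams(model="cage_hop", n_particles=500, n_steps=2000,
                         hop_rate=rate, cage_sigma=0.2, jump_length=ell, seed=11)
        curve = msd(gen_cage_hopper(p), max_lag=400.0)
        mask = curve.lag_times >= 100.0
        slopes = curve.msd[mask] / curve.lag_times[mask]
        assert np.mean(slopes) == pytest.approx(rate * ell ** 2, rel=0.1)

    def test_coarse_resolution_rejected(self):
        with pytest.raises(GelKineticsError, match="resolution"):
            gen_cage_hopper(WalkerParams(model="cage_hop", hop_rate=0.6, dt=1.0))


class TestRouse:
    def test_single_bead_is_free_brownian(self):
        p = RouseParams(n_beads=1, n_chains=200, dt=0.05, n_steps=1000, seed=12)
        curve = msd(gen_rouse(p), max_lag=25.0)
        fit = fit_power_law(curve, (0.5, 10.0))
        assert fit.alpha == pytest.approx(1.0, abs=0.05)

    def test_middle_bead_subdiffusion(self):
        p = RouseParams(n_beads=64, n_chains=50, dt=0.05, n_steps=3000, seed=13)
        traj = gen_rouse(p)
        curve = msd(traj, selection=middle_bead_label(p), max_lag=100.0,
                    origin_stride=5)
        fit = fit_power_law(curve, (3.0, 30.0))
        assert fit.alpha == pytest.approx(0.50, abs=0.05)

    def test_com_diffusion_scales_inversely_with_chain_length(self):
        # D_com = k_B T / (N zeta) = 1/64 in reduced units
        p = RouseParams(n_beads=64, n_chains=150, dt=0.05, n_steps=1500, seed=14)
        traj = gen_rouse(p)
        pos = traj.positions.reshape(traj.n_frames, p.n_chains, p.n_beads, 3)
        from gelkinetics.trajectory import Trajectory
        com = Trajectory(positions=pos.mean(axis=2), dt=p.dt)
        curve = msd(com, max_lag=40.0, origin_stride=10)
        mask = curve.lag_times >= 10.0
        d = np.polyfit(curve.lag_times[mask], curve.msd[mask], 1)[0] / 6.0
        assert d == pytest.approx(1.0 / 64, rel=0.15)

    def test_unstable_timestep_rejected(self):
        with pytest.raises(GelKineticsError, match="unstable"):
            gen_rouse(RouseParams(n_beads=16, dt=0.3, spring_constant=1.0))


class TestPacking:
    def test_lattice_nearest_neighbor_is_spacing(self):
        conf = gen_packing("lattice", 27, box=6.0, spacing=2.0)
        d = conf.positions[:, None, :] - conf.positions[None, :, :]
        d -= 6.0 * np.round(d / 6.0)
        r = np.sqrt((d ** 2).sum(axis=2))
        np.fill_diagonal(r, np.inf)
        assert r.min() == pytest.approx(2.0)

    def test_poisson_rdf_is_flat(self):
        conf = gen_packing("poisson", 3000, box=20.0, seed=15)
        curve = rdf(conf, dr=0.25, r_max=10.0)
        mask = curve.bin_centers > 1.0
        assert abs(curve.g[mask].mean() - 1.0) < 0.02
        assert np.abs(curve.g[mask] - 1.0).max() < 0.1

    def test_overfilled_lattice_rejected(self):
        with pytest.raises(GelKineticsError, match="overfilled"):
            gen_packing("lattice", 27, box=5.0, spacing=2.0)

    def test_seed_reproducibility(self):
        a = gen_packing("poisson", 50, box=10.0, seed=3)
        b = gen_packing("poisson", 50, box=10.0, seed=3)
        assert np.array_equal(a.positions, b.positions)


class TestHBondFixture:
    def test_collinear_triple(self):
        conf = gen_hbond_fixture([(2.9, 1.9, 0.0)])
        d, h, a = conf.positions
        assert np.linalg.norm(a - d) == pytest.approx(2.9)
        assert np.linalg.norm(a - h) == pytest.approx(1.9)
        # collinear: D-H and H-A directions coincide
        cross = np.cross(h - d, a - h)
        assert np.linalg.norm(cross) == pytest.approx(0.0, abs=1e-12)

    def test_threshold_geometry_realized_exactly(self):
        conf = gen_hbond_fixture([(3.5, 2.4, 29.0)])
        d, h, a = conf.positions
        assert np.linalg.norm(a - d) == pytest.approx(3.5)
        assert np.linalg.norm(a - h) == pytest.approx(2.4)
        v1, v2 = d - h, a - h
        ang = math.degrees(math.acos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
        assert 180.0 - ang == pytest.approx(29.0, abs=1e-9)

    def test_unrealizable_geometry_rejected(self):
        with pytest.raises(GelKineticsError, match="unrealizable"):
            gen_hbond_fixture([(1.0, 2.4, 0.0)])  # d_DA < d_HA at near-linearity

    def test_empty_list_gives_empty_configuration(self):
        assert gen_hbond_fixture([]).n_atoms == 0


class TestBilinearVT:
    def test_noiseless_series_is_exactly_bilinear(self):
        series = gen_bilinear_vt(BilinearVTParams(t_break=425.0, noise_sd=0.0))
        t, v = series.temperatures, series.volumes
        below, above = t < 425.0, t >= 425.0
        assert np.allclose(np.diff(v[below]) / np.diff(t[below]), 0.5)
        assert np.allclose(np.diff(v[above]) / np.diff(t[above]), 1.2)
        assert series.true_break == 425.0

    def test_default_cooling_grid_has_19_points(self):
        series = gen_bilinear_vt(BilinearVTParams())
        assert len(series.temperatures) == 19
        assert series.temperatures.min() == 200.0
        assert series.temperatures.max() == 650.0

    def test_equal_slopes_flagged_degenerate(self):
        series = gen_bilinear_vt(BilinearVTParams(slope_low=0.7, slope_high=0.7))
        assert series.degenerate

    def test_break_outside_grid_rejected(self):
        with pytest.raises(GelKineticsError, match="outside the grid"):
            gen_bilinear_vt(BilinearVTParams(t_break=700.0))
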
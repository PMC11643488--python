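"""Anomalous-diffusion exponent recovery on synthetic walkers.

Generates ensembles with known ground-truth MSD exponents -- Brownian
(alpha = 1), fractional Brownian motion (alpha = 2H), a heavy-tailed CTRW
(alpha = mu) and an ideal Rouse chain middle monomer (alpha ~ 0.5) -- then
fits <r^2(t)> = K_alpha t^alpha on log-log axes.  Fitted alpha should match
the ground truth to within a few percent; this is the same analysis used to
classify water transport in hydrogels as subdiffusive or Brownian.
"""
from gelkinetics import (RouseParams, WalkerParams, fit_power_law,
                        gen_brownian, gen_ctrw, gen_fbm, gen_rouse,
                        middle_bead_label, msd)

print("model              ground truth   fitted alpha")

traj = gen_brownian(WalkerParams(model="brownian", n_particles=500,
                                 n_steps=2000, diffusion=1e-5, seed=1))
fit = fit_power_law(msd(traj, max_lag=500.0), (10.0, 100.0))
print(f"brownian                 1.00        {fit.alpha:.3f}")

traj = gen_fbm(WalkerParams(model="fbm", n_particles=500, n_steps=1024,
                            hurst=0.35, seed=2))
fit = fit_power_law(msd(traj, max_lag=1000.0), (5.0, 500.0))
print(f"fBM (H = 0.35)           0.70        {fit.alpha:.3f}")

traj = gen_ctrw(WalkerParams(model="ctrw", n_particles=1000, n_steps=2000,
                             waiting_exponent=0.7, jump_length=1.0, seed=3))
# the CTRW ages: use the fixed-origin ensemble MSD, not sliding origins
fit = fit_power_law(msd(traj, max_lag=2000.0, origin_stride=10 ** 9),
                    (20.0, 2000.0))
print(f"CTRW (mu = 0.7)          0.70        {fit.alpha:.3f}")

params = RouseParams(n_beads=64, n_chains=50, dt=0.05, n_steps=3000, seed=4)
traj = gen_rouse(params)
curve = msd(traj, selection=middle_bead_label(params), max_lag=100.0,
            origin_stride=5)
fit = fit_power_law(curve, (3.0, 30.0))
print(f"Rouse middle bead        0.50        {fit.alpha:.3f}")
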
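# Methods

This note documents the models implemented in gelkinetics, the defaults and
units, the synthetic ground-truth generators, and the numerical choices
that make results reproducible.

## Units and conventions

Internal units are Ångström and picosecond. Diffusion coefficients are
accepted and reported in cm²/s (1 Å²/ps = 10⁻⁴ cm²/s), matching how water
diffusivities in hydrogels are usually quoted. Boxes are cubic and
periodic with the origin at a corner; wrapped coordinates live in [0, L).
All pair distances use the minimum-image convention. Trajectory text I/O
is an extended-XYZ dialect whose comment line carries
`box_edge=… time=… wrapped=…` key=value pairs, written with 6 decimals
(below any analysis tolerance); unwrapping reconstructs continuous
coordinates by cumulative minimum image and is valid only while true
per-frame displacements stay below L/2 (steps exactly at L/2 raise).

## Hydration stoichiometry

A cell holds one 50-mer chain plus water. Chain masses are bare mer sums
over IUPAC abridged atomic weights (H 1.008, C 12.011, N 14.007,
O 15.999); end groups are excluded by default because capping chemistry is
rarely specified, with an optional `end_group_mass` for when it is. The
water count solves n = (f/(1−f))·M_chain/18.015 and rounds to the nearest
integer (ties away from zero); this reproduces the published 10–40%
counts for all five named chains exactly. At 60% water the published
counts sit one molecule above bare-mass stoichiometry (consistent with
≈16 g/mol of unreported end-group mass), so they are not used as exact
checks. The cubic edge follows from L³ = M_cell/(N_A ρ) with the target
density 1.1 g/cm³. The five named compositions follow the prose counts
(R37 = 37 HEMA + 13 VP); the run-length sequences attached to the two
random copolymers are assigned so their expanded counts agree with those
labels.

## Synthetic generators

Every generator is deterministic under its integer seed, and each exists
to give one analysis a known answer:

* **Brownian walkers** — i.i.d. Gaussian increments, per-axis variance
  2DΔt. Ground truth: MSD exponent α = 1 and the Einstein D itself.
  D = 0 produces static particles.
* **Fractional Brownian motion** — each axis an exact fGn path via
  circulant (Davies–Harte) embedding of the closed-form autocovariance,
  not approximate subordination, so the scaling MSD ∝ t^{2H} holds at all
  lags. Ground truth: α = 2H.
* **CTRW** — Pareto waiting times with exponent μ ∈ (0,1) (minimum wait
  Δt) and isotropic Gaussian jumps. The ensemble MSD grows as t^μ at long
  times. Two caveats are inherent to the model, not defects: the process
  *ages*, so the exponent must be measured on the fixed-origin ensemble
  MSD (sliding-origin averaging famously returns α ≈ 1 — weak ergodicity
  breaking), and convergence to the asymptotic exponent is slow for small
  μ (at μ = 0.3 the effective exponent at 10³–10⁴ waiting-time units is
  still ≈ 0.39). Recovery tests therefore use μ ≥ 0.5 for the CTRW and
  realize smaller target exponents with fBM.
* **Cage hopper** — position = cage center + stationary Ornstein–Uhlenbeck
  rattle (s.d. `cage_sigma`, relaxation `cage_tau`, default Δt); the
  center jumps a fixed distance `jump_length` in a random direction at
  Poisson rate `hop_rate` (rejected when `hop_rate·Δt > 0.5`, where the
  Bernoulli-per-step approximation and mode resolution break down).
  Ground truth: a bimodal 4πr²G_s with second mode at the jump length when
  the lag holds ~1 hop, and long-time MSD slope `hop_rate·jump_length²`.
* **Rouse chains** — overdamped Euler–Maruyama integration of phantom
  harmonic bead-spring chains in reduced units (k_BT = 1), initialized
  from exact equilibrium (i.i.d. Gaussian bond vectors), so time-origin
  averaging is stationary from the first frame. Stability requires
  Δt·k/ζ < 0.25; the default Δt = 0.05 at k = ζ = 1 keeps Euler bias well
  below the statistical error at the ensemble sizes used. Ground truth:
  middle-monomer α ≈ 0.5 between the bond relaxation time ζ/4k = 0.25 and
  the slowest Rouse time ≈ ζN²/π²k (≈ 415 for N = 64), and
  D_com = k_BT/Nζ.
* **Packings** (simple-cubic / Poisson) for RDF and free-volume checks,
  **explicit D–H···A geometries** built by law-of-cosines placement for the
  hydrogen-bond detector (the covalent D–H distance is whatever the
  requested triangle implies), and **bilinear V(T) series** on the
  650→200 K, 25 K cooling grid with Gaussian noise and a known breakpoint.

What the generators deliberately do **not** emulate: force fields,
thermostats/barostats, excluded volume, electrostatics, real water
structure, or cross-linked network topology. Passing tests therefore
demonstrate that the *analyses* are correct on processes with the assumed
statistical structure — not that any particular force field reproduces
experiment.

## Analyses

**MSD and power-law fits.** ⟨r²(t)⟩ averages over particles and sliding
time origins (stride configurable; overlapping origins by default, which
reduces variance and is consistent for stationary processes). Lags are
log-spaced, ~20 per decade, with lag 0 included (MSD(0) = 0). The fit
window is always explicit — defaulting to one inner decade of available
lags — because fitted exponents depend on it; α and K_α come from least
squares on log₁₀MSD vs log₁₀t.

**Diffusion.** D = slope/6 of the particle-averaged MSD over the linear
window. (Combining a 1/6N prefactor with an MSD already averaged over the
N particles would double-count N; the implemented convention recovers the
generator D to within sampling error.) If the local power-law exponent on
the window leaves [0.9, 1.1] the result carries a non-linearity warning
rather than being rejected.

**Van Hove self-part.** Radial histogram of displacement magnitudes over
particles and origins; shell mass 4πr²G_s·dr is normalized to sum to 1 per
lag, and the analysis refuses to drop probability mass (displacements
beyond r_max raise rather than being silently truncated), which makes the
second-moment identity ∫r²G_s d³r = MSD testable to 1% with a bin width
well below the displacement scale (binning bias ~dr²/12). Mode detection
smooths the shell mass with a 3-bin moving average and reports local
maxima with prominence ≥ 5% of the curve maximum (zero-padded so a
boundary maximum at r → 0 counts); the defaults are fixed so mode counts
are reproducible.

**RDF.** Shell counts normalized by the ideal-gas expectation with exact
shell volumes, frames averaged, self-pairs excluded on overlapping
selections; r_max ≤ L/2 enforced rather than silently truncated. The
first-peak extractor returns the first local maximum above a height
threshold and `None` for peakless (ideal-gas) curves; plateaus do not
count as peaks.

**Hydrogen bonds.** Hydrogens are paired covalently to their nearest donor
within `max_dh` (default 1.25 Å — chosen to cover the slightly stretched
D–H distances that exactly-at-threshold test geometries imply, while
staying far below the ≥1.5 Å range of genuine hydrogen-bond H···A
contacts); an orphan hydrogen is an error. A triple is a bond iff
d(D···A) ≤ 3.5 Å (inclusive), d(H···A) < 2.5 Å (exclusive) and the
deviation of the D–H···A angle from 180° is ≤ 30° (inclusive), evaluated
with a 10⁻⁹ guard so constructed boundary geometries follow the stated
inclusive/exclusive semantics despite float round-off. Detection is
all-pairs under minimum image and is verified against an independent
brute-force enumeration.

**Free volume.** Voxel centers farther than r_vdW + r_probe from every
atom are free; FFV = 100·free/total. The grid must satisfy
h ≤ r_probe/2 (or h ≤ 0.5 Å for the point probe); the box is divided into
an integer voxel count so the actual spacing may be slightly finer than
requested. Channels are connected components of free voxels under
6-connectivity merged across periodic faces by union–find. The analytic
one-sphere FFV is reproduced to < 0.1 percentage points at h = 0.25 Å.
Published FFV tables for real polymer cells are matched only in trend
(monotone decrease with probe radius, growth on stripping water), since
the reference grid resolution is unknown and the original configurations
are not available.

**Glass transition.** The continuous hinge model
V = V_b + s_low·min(T−T_g, 0) + s_high·max(T−T_g, 0) keeps T_g well
defined as the segment intersection. The breakpoint is located by grid
search over interior data temperatures (3 points excluded at each edge so
both segments are always identifiable) and refined by bounded scalar
minimization of the SSE between the neighbors of the best grid point;
noiseless bilinear data are recovered exactly regardless of break
position, and the estimate is invariant to temperature ordering
(ascending or the cooling protocol's descending). Residual bootstrap
(default 100 replicates, seeded) gives the breakpoint s.e. A fit with
indistinguishable slopes is flagged degenerate (T_g unreliable); a fit
with s_high < s_low is flagged unphysical for a glass transition.

## Problem sizes

The validation suite runs ensembles of 300–1000 walkers for 500–3000
steps, 50-chain Rouse ensembles of 64 beads, ≤3000-atom packings and
100-seed recovery studies — sizes chosen so each recovery statement is
comfortably inside its tolerance at a few seconds per check. The same
sizes are used by `scripts/acceptance.py`.

## Known limitations

* `read_pdb` handles single-model coordinate records only; no topology or
  CONECT parsing.
* Boxes are cubic; triclinic cells are out of scope.
* RDF and hydrogen-bond detection are O(N²) per frame (minimum-image
  correctness over neighbor-list speed at these problem sizes).
* The CTRW generator targets the subdiffusive regime μ ∈ (0,1) only;
  μ ≥ 1 belongs to the Brownian generator.
* Hydrogen-bond lifetimes, velocity/rotational correlations and
  solvent-accessible surface areas are not implemented.
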
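"""Probe-based fractional free volume and diffusion channels.

A single atom of vdW radius 2 A in a 10 A periodic box has an analytic FFV,
so the voxel estimate can be checked exactly.  A random packing then shows
the water-probe convention (1.4 A sphere) and how stripping a subset of
atoms -- the swollen-geometry trick used to measure the space available to
water -- enlarges the free volume and merges channels.
"""
import math

import numpy as np

from gelkinetics import Configuration, free_volume, gen_packing, strip_selection

conf = Configuration(positions=[[5.0, 5.0, 5.0]], box_edge=10.0, vdw_radii=[2.0])
res = free_volume(conf, probe_radius=0.0, grid_spacing=0.25)
exact = 100.0 * (1 - 4 * math.pi / 3 * 2.0 ** 3 / 1000.0)
print(f"point probe:  FFV = {res.ffv:.2f}%  (analytic {exact:.2f}%)")
res = free_volume(conf, probe_radius=1.4, grid_spacing=0.25)
exact = 100.0 * (1 - 4 * math.pi / 3 * 3.4 ** 3 / 1000.0)
print(f"water probe:  FFV = {res.ffv:.2f}%  (analytic {exact:.2f}%)")

# a random packing: half the sites labelled as removable "water"
pack = gen_packing("poisson", 100, box=16.0, seed=7)
pack.vdw_radii = np.full(100, 1.0)
pack.labels[:50] = "O_W"
full = free_volume(pack, probe_radius=1.0, grid_spacing=0.5)
dry = free_volume(strip_selection(pack, "O_W"), probe_radius=1.0, grid_spacing=0.5)
print(f"packing:      FFV = {full.ffv:.1f}% with all atoms, "
      f"{dry.ffv:.1f}% after removing the 'water' sites")
print(f"channels:     {full.n_channels} -> {dry.n_channels} "
      "(free volumes merge when atoms are removed)")
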
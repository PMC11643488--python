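"""Geometric hydrogen-bond detection with explicit boundary semantics.

Builds donor-hydrogen-acceptor triples at chosen geometries (D...A
distance, H...A distance, deviation of D-H...A from linearity) and runs the
detector.  The criteria are: D...A <= 3.5 A, H...A < 2.5 A, deviation
<= 30 degrees, all under minimum image.  The per-class counts use the
polymer site tags (hydroxyl/carbonyl/ether oxygens, ring nitrogen, water).
"""
from gelkinetics import detect_hbonds, gen_hbond_fixture, site_class_counts

geometries = [
    (2.9, 1.9, 10.0),   # comfortable hydrogen bond
    (3.5, 2.4, 30.0),   # exactly at every threshold -> still accepted
    (3.51, 2.4, 30.0),  # donor-acceptor 0.01 A too long -> rejected
    (3.0, 2.5, 0.0),    # H...A bound is exclusive -> rejected
]
conf = gen_hbond_fixture(geometries, donor_label="O_W", acceptor_label="O_H3")
hb = detect_hbonds(conf)
print(f"{len(hb)} of {len(geometries)} candidate triples accepted:")
for b in hb.bonds:
    print(f"  D{b.donor}-H{b.hydrogen}...A{b.acceptor}  d_DA={b.d_da:.2f} A "
          f"d_HA={b.d_ha:.2f} A  deviation={b.angle_dev:.0f} deg")
print("acceptor site classes:", hb.acceptor_class_counts)
print("atoms by site class:", site_class_counts(conf))
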
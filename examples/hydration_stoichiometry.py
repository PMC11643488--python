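"""Hydration stoichiometry and cell sizing for the five studied polymers.

For each 50-mer chain (PHEMA homopolymer and four VP/HEMA copolymers) this
prints, per target water mass fraction, the integer number of water
molecules that best realizes the fraction and the cubic cell edge at the
target density of 1.1 g/cm^3.  At 10-40% water the counts are exact
stoichiometric consequences of the mer formulas.
"""
from gelkinetics import chain_molar_mass, hydration_spec, named_polymer

for code in ("H50", "B37", "B13", "R37", "R13"):
    comp = named_polymer(code)
    print(f"\n{code}: {dict(comp.counts)}  M_chain = {chain_molar_mass(comp):.1f} g/mol")
    print("  water%   n_water   cell edge (A)")
    for frac in (0.0, 0.1, 0.2, 0.4, 0.6):
        spec = hydration_spec(comp, frac, density=1.1)
        print(f"  {100 * frac:5.0f}    {spec.n_water:6d}    {spec.cell_edge:10.3f}")
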
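"""Polymer composition bookkeeping, hydration stoichiometry and cell sizing.

The systems of interest are single 50-mer chains of 2-hydroxyethyl
methacrylate (HEMA, C6H10O3) and N-vinylpyrrolidone (VP, C6H9NO), dry or
hydrated, each occupying one cubic periodic cell.  Given a chain composition,
a target water mass fraction and a target density, this module computes the
integer number of water molecules that best realizes the mass fraction and
the cubic cell edge that realizes the density.

Masses are in g/mol, densities in g/cm^3, lengths in Angstrom.
"""
from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

from .errors import GelKineticsError

AVOGADRO = 6.02214076e23  # 1/mol
WATER_MOLAR_MASS = 18.015  # g/mol

#: IUPAC abridged standard atomic weights (g/mol) for the elements that occur
#: in the studied polymers and in water.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
}


def formula_mass(formula: Mapping[str, int]) -> float:
    """Molar mass of an element->count formula from standard atomic weights."""
    try:
        return float(sum(ATOMIC_MASS[el] * n for el, n in formula.items()))
    except KeyError as exc:  # pragma: no cover - trivial message path
        raise GelKineticsError(f"no atomic mass registered for element {exc}") from exc


@dataclass(frozen=True)
class MerSpec:
    """A repeat unit: short label plus elemental formula."""

    name: str
    formula: Mapping[str, int]

    @property
    def molar_mass(self) -> float:
        return formula_mass(self.formula)


#: Registry of known mers.  Additional mers can be added with
#: :func:`register_mer` or loaded from a YAML file with
#: :func:`load_mer_registry`.
MER_REGISTRY: dict[str, MerSpec] = {
    "HEMA": MerSpec("HEMA", {"C": 6, "H": 10, "O": 3}),
    "VP": MerSpec("VP", {"C": 6, "H": 9, "N": 1, "O": 1}),
}


def register_mer(spec: MerSpec) -> None:
    MER_REGISTRY[spec.name] = spec


def get_mer(name: str) -> MerSpec:
    try:
        return MER_REGISTRY[name]
    except KeyError:
        raise GelKineticsError(f"unknown mer label {name!r}; registered: {sorted(MER_REGISTRY)}")


def load_mer_registry(path) -> None:
    """Load additional mers from a YAML map ``{name: {element: count}}``."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    for name, formula in data.items():
        register_mer(MerSpec(str(name), {str(k): int(v) for k, v in formula.items()}))


@dataclass(frozen=True)
class ChainComposition:
    """An ordered mer sequence for one polymer chain."""

    sequence: tuple[str, ...]

    @property
    def counts(self) -> Counter:
        return Counter(self.sequence)

    @property
    def chain_length(self) -> int:
        return len(self.sequence)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int]) -> "ChainComposition":
        """Block arrangement with the given per-mer counts (order of the map)."""
        seq: list[str] = []
        for name, n in counts.items():
            seq.extend([name] * int(n))
        return cls(tuple(seq))


def _expand_runlength(code: str) -> tuple[str, ...]:
    """Expand e.g. 'H2V5H...' into a mer sequence (H->HEMA, V->VP)."""
    out: list[str] = []
    for letter, num in re.findall(r"([HV])(\d*)", code):
        out.extend(["HEMA" if letter == "H" else "VP"] * (int(num) if num else 1))
    return tuple(out)


# The five studied chains, all 50 mers long.  Block copolymers are named by
# their HEMA count (B37 = 13 VP + 37 HEMA).  The random sequences below carry
# the counts stated for each code in prose (R37: 37 HEMA + 13 VP; R13: 13
# HEMA + 37 VP).
_NAMED_SEQUENCES: dict[str, tuple[str, ...]] = {
    "H50": ("HEMA",) * 50,
    "B37": ("VP",) * 13 + ("HEMA",) * 37,
    "B13": ("VP",) * 37 + ("HEMA",) * 13,
    "R37": _expand_runlength("HV2H8V3H3V2H2VH6VH10V2H4VH3V"),
    "R13": _expand_runlength("H2V5H2V6H2V2HV10HVH2V6HV6H2V"),
}


def named_polymer(code: str) -> ChainComposition:
    """Return the composition of one of the five studied chains.

    Codes: ``H50`` (PHEMA homopolymer), ``B37``/``B13`` (block copolymers with
    37/13 HEMA mers), ``R37``/``R13`` (random copolymers with 37/13 HEMA mers).
    """
    try:
        return ChainComposition(_NAMED_SEQUENCES[code])
    except KeyError:
        raise GelKineticsError(
            f"unknown polymer code {code!r}; known: {sorted(_NAMED_SEQUENCES)}"
        )


def chain_molar_mass(composition: ChainComposition, end_group_mass: float = 0.0) -> float:
    """Molar mass of the chain as the sum of its mer masses.

    End groups (chain caps) are excluded by default; pass ``end_group_mass``
    to add a fixed extra mass for capping chemistry.
    """
    return sum(get_mer(name).molar_mass for name in composition.sequence) + end_group_mass


def water_count(
    composition: ChainComposition,
    mass_fraction: float,
    end_group_mass: float = 0.0,
) -> int:
    """Number of water molecules realizing a target water mass fraction.

    Solves n = (f/(1-f)) * M_chain / m_water and rounds to the nearest
    integer (ties away from zero).
    """
    if not 0.0 <= mass_fraction < 1.0:
        raise GelKineticsError(f"water mass fraction must be in [0, 1), got {mass_fraction}")
    m_chain = chain_molar_mass(composition, end_group_mass)
    n = (mass_fraction / (1.0 - mass_fraction)) * m_chain / WATER_MOLAR_MASS
    return int(math.floor(n + 0.5))


def achieved_mass_fraction(
    composition: ChainComposition, n_water: int, end_group_mass: float = 0.0
) -> float:
    """Water mass fraction actually realized by an integer molecule count."""
    m_chain = chain_molar_mass(composition, end_group_mass)
    m_w = n_water * WATER_MOLAR_MASS
    return m_w / (m_chain + m_w)


def cell_edge(total_mass: float, density: float) -> float:
    """Cubic cell edge (Angstrom) for a per-cell molar mass at a density.

    ``total_mass`` is the molar mass of the whole cell contents (g/mol),
    ``density`` in g/cm^3.  One formula unit per cell is assumed.
    """
    if total_mass <= 0 or density <= 0:
        raise GelKineticsError("total_mass and density must be positive")
    volume_cm3 = total_mass / (AVOGADRO * density)
    return volume_cm3 ** (1.0 / 3.0) * 1e8


@dataclass(frozen=True)
class HydrationSpec:
    """One hydrated-cell recipe: chain + integer water count + cell sizing."""

    composition: ChainComposition
    water_mass_fraction: float
    n_water: int
    density: float
    cell_edge: float

    @property
    def achieved_mass_fraction(self) -> float:
        return achieved_mass_fraction(self.composition, self.n_water)


def hydration_spec(
    composition: ChainComposition,
    mass_fraction: float,
    density: float = 1.1,
    end_group_mass: float = 0.0,
) -> HydrationSpec:
    """Full hydration recipe at a target mass fraction and density.

    The default density of 1.1 g/cm^3 is the equilibrated-cell target used
    for these hydrogels.
    """
    n = water_count(composition, mass_fraction, end_group_mass)
    total = chain_molar_mass(composition, end_group_mass) + n * WATER_MOLAR_MASS
    return HydrationSpec(
        composition=composition,
        water_mass_fraction=mass_fraction,
        n_water=n,
        density=density,
        cell_edge=cell_edge(total, density),
    )
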
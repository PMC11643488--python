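"""Configurations, trajectories, text I/O and periodic wrap management.

Boxes are cubic and periodic with the origin at a corner; wrapped
coordinates live in the half-open interval [0, L).  Trajectories are stored
as a single (n_frames, n_atoms, 3) array with shared per-atom metadata.

The on-disk trajectory format is an extended XYZ dialect: the per-frame
comment line carries ``box_edge=<A> time=<ps> wrapped=<0|1>`` key=value
pairs, and atom lines are ``label x y z [element hbond_role]``.  A minimal
single-model PDB reader (via biotite) is provided for convenience.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .errors import GelKineticsError

#: Default van der Waals radii (Angstrom) by element for the atoms forming
#: the studied polymers and water.
DEFAULT_VDW: dict[str, float] = {"C": 1.70, "H": 1.20, "O": 1.52, "N": 1.55}

#: Valid hydrogen-bond role annotations.
HBOND_ROLES = ("none", "donor", "hydrogen", "acceptor")

COORD_DECIMALS = 6  # fixed text output precision (Angstrom)


def _as_str_array(values, n: int, default: str) -> np.ndarray:
    if values is None:
        return np.full(n, default, dtype=object)
    arr = np.asarray(values, dtype=object)
    if arr.shape != (n,):
        raise GelKineticsError(f"per-atom annotation has shape {arr.shape}, expected ({n},)")
    return arr


@dataclass
class Configuration:
    """A single frame: positions plus per-atom annotations.

    ``vdw_radii`` defaults from ``elements`` via :data:`DEFAULT_VDW` when
    elements are known; analyses that need radii raise otherwise.
    """

    positions: np.ndarray
    box_edge: Optional[float] = None
    labels: Optional[np.ndarray] = None
    elements: Optional[np.ndarray] = None
    vdw_radii: Optional[np.ndarray] = None
    hbond_roles: Optional[np.ndarray] = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise GelKineticsError(f"positions must be (n, 3), got {self.positions.shape}")
        if not np.all(np.isfinite(self.positions)):
            raise GelKineticsError("positions must be finite")
        n = self.n_atoms
        self.labels = _as_str_array(self.labels, n, "X")
        if self.elements is not None:
            self.elements = _as_str_array(self.elements, n, "")
        if self.hbond_roles is not None:
            self.hbond_roles = _as_str_array(self.hbond_roles, n, "none")
            bad = set(self.hbond_roles) - set(HBOND_ROLES)
            if bad:
                raise GelKineticsError(f"unknown hbond roles {sorted(bad)}")
        if self.vdw_radii is None and self.elements is not None:
            try:
                self.vdw_radii = np.array([DEFAULT_VDW[e] for e in self.elements])
            except KeyError as exc:
                raise GelKineticsError(f"no default vdW radius for element {exc}") from exc
        elif self.vdw_radii is not None:
            self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
            if self.vdw_radii.shape != (n,):
                raise GelKineticsError("vdw_radii must have one entry per atom")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def require_box(self) -> float:
        if self.box_edge is None or self.box_edge <= 0:
            raise GelKineticsError("this analysis requires a positive periodic box_edge")
        return float(self.box_edge)

    def select(self, selection) -> np.ndarray:
        return resolve_selection(self.labels, selection)


@dataclass
class Trajectory:
    """Time-ordered frames with constant atom count and ordering.

    ``positions`` has shape (n_frames, n_atoms, 3); ``dt`` is the frame
    spacing in ps; ``wrapped`` records whether coordinates are folded into
    the box.
    """

    positions: np.ndarray
    dt: float
    box_edge: Optional[float] = None
    labels: Optional[np.ndarray] = None
    elements: Optional[np.ndarray] = None
    hbond_roles: Optional[np.ndarray] = None
    wrapped: bool = False

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise GelKineticsError(f"positions must be (frames, atoms, 3), got {self.positions.shape}")
        if self.dt <= 0:
            raise GelKineticsError("frame spacing dt must be positive")
        n = self.n_atoms
        self.labels = _as_str_array(self.labels, n, "X")
        if self.elements is not None:
            self.elements = _as_str_array(self.elements, n, "")
        if self.hbond_roles is not None:
            self.hbond_roles = _as_str_array(self.hbond_roles, n, "none")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.dt

    def frame(self, i: int) -> Configuration:
        return Configuration(
            positions=self.positions[i],
            box_edge=self.box_edge,
            labels=self.labels,
            elements=self.elements,
            hbond_roles=self.hbond_roles,
        )

    def select(self, selection) -> np.ndarray:
        return resolve_selection(self.labels, selection)


Selection = Union[None, str, Sequence[str], Sequence[int], np.ndarray]


def resolve_selection(labels: np.ndarray, selection: Selection,
                      allow_empty: bool = False) -> np.ndarray:
    """Resolve a selection to integer atom indices.

    ``None`` selects everything; a string or set of strings matches labels;
    an integer sequence/array is taken as indices directly.  An empty match
    raises unless ``allow_empty``.
    """
    n = len(labels)
    if selection is None:
        return np.arange(n)
    if isinstance(selection, str):
        idx = np.flatnonzero(np.asarray([l == selection for l in labels]))
    else:
        arr = np.asarray(selection)
        if arr.dtype.kind in "iub":
            idx = np.arange(n)[arr] if arr.dtype.kind == "b" else arr.astype(int)
        else:
            wanted = set(map(str, selection))
            idx = np.flatnonzero(np.asarray([str(l) in wanted for l in labels]))
    if len(idx) == 0 and not allow_empty:
        raise GelKineticsError(f"selection {selection!r} matches no atoms")
    return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# extended XYZ

def _format_frame(out, pos, labels, elements, roles, box_edge, time, wrapped):
    n = pos.shape[0]
    meta = []
    if box_edge is not None:
        meta.append(f"box_edge={box_edge:.{COORD_DECIMALS}f}")
    meta.append(f"time={time:.{COORD_DECIMALS}f}")
    meta.append(f"wrapped={1 if wrapped else 0}")
    out.append(str(n))
    out.append(" ".join(meta))
    extra = elements is not None or roles is not None
    el = elements if elements is not None else ["X"] * n
    rl = roles if roles is not None else ["none"] * n
    for i in range(n):
        line = f"{labels[i]} {pos[i,0]:.{COORD_DECIMALS}f} {pos[i,1]:.{COORD_DECIMALS}f} {pos[i,2]:.{COORD_DECIMALS}f}"
        if extra:
            line += f" {el[i]} {rl[i]}"
        out.append(line)


def write_xyz(obj: Union[Trajectory, Configuration], path) -> None:
    """Write a trajectory or single configuration in the extended XYZ dialect."""
    out: list[str] = []
    if isinstance(obj, Configuration):
        _format_frame(out, obj.positions, obj.labels, obj.elements, obj.hbond_roles,
                      obj.box_edge, 0.0, False)
    else:
        for i in range(obj.n_frames):
            _format_frame(out, obj.positions[i], obj.labels, obj.elements,
                          obj.hbond_roles, obj.box_edge, i * obj.dt, obj.wrapped)
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")


def _parse_meta(comment: str) -> dict:
    meta = {}
    for tok in comment.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            meta[k] = v
    return meta


def read_xyz(path) -> Trajectory:
    """Read an extended-XYZ trajectory; single-frame files get dt=1 ps."""
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    frames, times, metas = [], [], []
    labels = elements = roles = None
    i, iframe = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise GelKineticsError(f"frame {iframe}: expected atom count, got {lines[i]!r}")
        if i + 1 + n >= len(lines) + 1 and i + 1 + n > len(lines):
            raise GelKineticsError(f"frame {iframe}: declared {n} atoms but file is truncated")
        meta = _parse_meta(lines[i + 1])
        pos = np.empty((n, 3))
        labs, els, rls = [], [], []
        for j in range(n):
            if i + 2 + j >= len(lines):
                raise GelKineticsError(f"frame {iframe}: declared {n} atoms, found {j} coordinate lines")
            parts = lines[i + 2 + j].split()
            if len(parts) < 4:
                raise GelKineticsError(f"frame {iframe}: malformed atom line {lines[i+2+j]!r}")
            labs.append(parts[0])
            try:
                pos[j] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise GelKineticsError(f"frame {iframe}: non-numeric coordinates in {lines[i+2+j]!r}")
            if len(parts) >= 6:
                els.append(parts[4])
                rls.append(parts[5])
        if frames and n != frames[0].shape[0]:
            raise GelKineticsError(
                f"frame {iframe}: particle count {n} differs from first frame {frames[0].shape[0]}")
        if labels is None:
            labels = np.asarray(labs, dtype=object)
            elements = np.asarray(els, dtype=object) if els else None
            roles = np.asarray(rls, dtype=object) if rls else None
        frames.append(pos)
        times.append(float(meta.get("time", iframe)))
        metas.append(meta)
        i += 2 + n
        iframe += 1
    if not frames:
        raise GelKineticsError("empty trajectory file")
    box = metas[0].get("box_edge")
    wrapped = metas[0].get("wrapped", "0") not in ("0", "false", "False")
    if len(times) > 1:
        diffs = np.diff(times)
        if not np.allclose(diffs, diffs[0], rtol=1e-6, atol=1e-9):
            raise GelKineticsError("non-uniform frame times in trajectory file")
        dt = float(diffs[0])
    else:
        dt = 1.0
    return Trajectory(
        positions=np.stack(frames),
        dt=dt,
        box_edge=float(box) if box is not None else None,
        labels=labels,
        elements=elements,
        hbond_roles=roles,
        wrapped=wrapped,
    )


def read_configuration(path) -> Configuration:
    """Read a single-frame extended-XYZ file as a Configuration."""
    traj = read_xyz(path)
    return traj.frame(0)


# ---------------------------------------------------------------------------
# minimal PDB

def read_pdb(path) -> Configuration:
    """Read a single-model PDB file into a Configuration.

    Elements come from the PDB element column and are mapped to default vdW
    radii; a cubic CRYST1 record, if present, populates ``box_edge``.
    """
    import biotite.structure.io.pdb as pdb

    pdbfile = pdb.PDBFile.read(str(path))
    atoms = pdbfile.get_structure(model=1)
    elements = np.asarray([e.capitalize() for e in atoms.element], dtype=object)
    if any(e.strip() == "" for e in elements):
        raise GelKineticsError("PDB file has atoms without an element assignment")
    unknown = sorted(set(elements) - set(DEFAULT_VDW))
    if unknown:
        raise GelKineticsError(f"unknown element symbols in PDB: {unknown}")
    box_edge = None
    box = atoms.box
    if box is not None:
        lengths = np.linalg.norm(np.asarray(box), axis=-1)
        if np.allclose(lengths, lengths[0], rtol=1e-6) and lengths[0] > 0:
            box_edge = float(lengths[0])
    return Configuration(
        positions=np.asarray(atoms.coord, dtype=float),
        box_edge=box_edge,
        labels=np.asarray(atoms.atom_name, dtype=object),
        elements=elements,
    )


# ---------------------------------------------------------------------------
# wrap state

def wrap(traj: Trajectory) -> Trajectory:
    """Fold all coordinates into [0, L)."""
    if traj.box_edge is None or traj.box_edge <= 0:
        raise GelKineticsError("wrap requires a positive box_edge")
    L = traj.box_edge
    return replace(traj, positions=np.mod(traj.positions, L), wrapped=True)


def unwrap(traj: Trajectory) -> Trajectory:
    """Reconstruct continuous coordinates by cumulative minimum image.

    Requires every true per-frame displacement to be below L/2 per axis;
    exactly ambiguous (|d| == L/2) steps raise.
    """
    if not traj.wrapped:
        return replace(traj)
    if traj.box_edge is None or traj.box_edge <= 0:
        raise GelKineticsError("unwrap requires a positive box_edge")
    L = traj.box_edge
    d = np.diff(traj.positions, axis=0)
    d -= L * np.round(d / L)
    if np.any(np.isclose(np.abs(d), L / 2.0, rtol=0, atol=1e-9)):
        raise GelKineticsError(
            "ambiguous unwrap: a per-frame displacement equals half the box edge")
    pos = np.concatenate([traj.positions[:1], traj.positions[:1] + np.cumsum(d, axis=0)])
    return replace(traj, positions=pos, wrapped=False)
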
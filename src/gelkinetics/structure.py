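"""Static-structure analyses: radial distribution functions, geometric
hydrogen-bond detection, site classification, and probe-based free volume.

All pair distances use the minimum-image convention in a cubic periodic
box.  Hydrogen bonds D-H...A follow geometric criteria: donor-acceptor
distance at most 3.5 A (inclusive), hydrogen-acceptor distance below 2.5 A
(exclusive), and deviation of the D-H...A angle from linearity at most 30
degrees (inclusive).  Free volume is estimated on a voxel grid: a voxel
center is free when it lies farther than (vdW radius + probe radius) from
every atom; the fractional free volume (FFV) is the free fraction of the
cell volume, and channels are periodic 6-connected components of free
voxels.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .errors import GelKineticsError
from .trajectory import Configuration, Selection, Trajectory, resolve_selection

_EPS = 1e-9  # guard so exactly-at-threshold geometries follow the stated semantics


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    return d - box * np.round(d / box)


@dataclass
class RDFCurve:
    bin_centers: np.ndarray  # A
    g: np.ndarray
    pair_labels: tuple
    dr: float
    n_frames: int


def _iter_frames(frames) -> list[Configuration]:
    if isinstance(frames, Configuration):
        return [frames]
    if isinstance(frames, Trajectory):
        return [frames.frame(i) for i in range(frames.n_frames)]
    return list(frames)


def rdf(
    frames: Union[Configuration, Trajectory, Sequence[Configuration]],
    selection_a: Selection = None,
    selection_b: Selection = None,
    dr: float = 0.1,
    r_max: Optional[float] = None,
) -> RDFCurve:
    """Radial distribution function g(r) between two selections.

    Shell counts under minimum image are normalized by the ideal-gas
    expectation (exact shell volumes), averaged over frames; pairs sharing
    an atom index are excluded when the selections overlap.  ``r_max``
    defaults to half the box edge and may not exceed it.
    """
    confs = _iter_frames(frames)
    if not confs:
        raise GelKineticsError("rdf needs at least one frame")
    box = confs[0].require_box()
    if r_max is None:
        r_max = box / 2.0
    if r_max > box / 2.0 + 1e-9:
        raise GelKineticsError(f"r_max={r_max} A exceeds half the box edge {box/2.0} A")
    if dr <= 0 or r_max <= dr:
        raise GelKineticsError("need 0 < dr < r_max")
    edges = np.arange(0.0, r_max + dr * 0.5, dr)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hist = np.zeros(len(centers))
    norm = np.zeros(len(centers))
    shell_vol = 4.0 / 3.0 * math.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    for conf in confs:
        ia = conf.select(selection_a)
        ib = conf.select(selection_b)
        pa, pb = conf.positions[ia], conf.positions[ib]
        d = _min_image(pa[:, None, :] - pb[None, :, :], box)
        r = np.sqrt(np.sum(d * d, axis=2))
        overlap = np.isin(ia, ib)
        if overlap.any():
            same = ia[:, None] == ib[None, :]
            r = r[~same].ravel()
            n_pairs = len(ia) * len(ib) - int(overlap.sum())
        else:
            r = r.ravel()
            n_pairs = len(ia) * len(ib)
        h, _ = np.histogram(r, bins=edges)
        hist += h
        norm += n_pairs * shell_vol / box ** 3
    g = np.divide(hist, norm, out=np.zeros_like(hist), where=norm > 0)
    la = selection_a if isinstance(selection_a, str) else "A"
    lb = selection_b if isinstance(selection_b, str) else "B"
    return RDFCurve(bin_centers=centers, g=g, pair_labels=(la, lb),
                    dr=dr, n_frames=len(confs))


def first_peak(curve: RDFCurve, min_height: float = 1.0) -> Optional[float]:
    """Center of the first local maximum of g(r) with g >= min_height.

    Returns ``None`` when no qualifying peak exists (e.g. a flat ideal-gas
    curve).
    """
    g = curve.g
    for i in range(len(g)):
        left = g[i - 1] if i > 0 else -np.inf
        # at the right edge fall back to the left neighbor so plateaus
        # (e.g. g == 1 everywhere) never count as peaks
        right = g[i + 1] if i + 1 < len(g) else g[i - 1] if i > 0 else np.inf
        if g[i] >= min_height and g[i] >= left and g[i] > right:
            return float(curve.bin_centers[i])
    return None


# ---------------------------------------------------------------------------
# hydrogen bonds

@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond criteria (defaults as stated above).

    ``max_dh`` is the covalent pairing cutoff used to associate each
    hydrogen with its nearest donor heavy atom.
    """

    max_da: float = 3.5  # A, inclusive
    max_ha: float = 2.5  # A, exclusive
    max_angle_dev: float = 30.0  # degrees from linearity, inclusive
    max_dh: float = 1.25  # A, covalent donor-hydrogen pairing cutoff

    def __post_init__(self):
        if min(self.max_da, self.max_ha, self.max_angle_dev, self.max_dh) <= 0:
            raise GelKineticsError("all hydrogen-bond criteria must be positive")
        if self.max_ha >= self.max_da:
            raise GelKineticsError("max_ha must be smaller than max_da")


@dataclass
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    d_da: float
    d_ha: float
    angle_dev: float


@dataclass
class HBondSet:
    bonds: list
    criteria: HBondCriteria
    donor_class_counts: dict = field(default_factory=dict)
    acceptor_class_counts: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.bonds)


def _hbond_geometry(pd, ph, pa, box):
    """(d_DA, d_HA, angle deviation from linearity in degrees)."""
    v_da = _min_image(pa - pd, box) if box else pa - pd
    v_hd = _min_image(pd - ph, box) if box else pd - ph
    v_ha = _min_image(pa - ph, box) if box else pa - ph
    d_da = float(np.linalg.norm(v_da))
    d_ha = float(np.linalg.norm(v_ha))
    cosang = float(np.dot(v_hd, v_ha) / (np.linalg.norm(v_hd) * d_ha))
    theta = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
    return d_da, d_ha, 180.0 - theta


def pair_hydrogens_to_donors(config: Configuration, max_dh: float = 1.25) -> dict[int, int]:
    """Associate each hydrogen-role atom with its nearest donor within
    ``max_dh`` A (minimum image).  A hydrogen with no such donor raises."""
    roles = config.hbond_roles
    if roles is None:
        raise GelKineticsError("configuration carries no hydrogen-bond role annotations")
    box = config.box_edge
    h_idx = np.flatnonzero(roles == "hydrogen")
    d_idx = np.flatnonzero(roles == "donor")
    pairing = {}
    if len(h_idx) == 0:
        return pairing
    if len(d_idx) == 0:
        raise GelKineticsError("hydrogens present but no donor atoms annotated")
    dvec = config.positions[h_idx][:, None, :] - config.positions[d_idx][None, :, :]
    if box:
        dvec = _min_image(dvec, box)
    dist = np.sqrt(np.sum(dvec * dvec, axis=2))
    nearest = np.argmin(dist, axis=1)
    for k, h in enumerate(h_idx):
        dmin = dist[k, nearest[k]]
        if dmin > max_dh + _EPS:
            raise GelKineticsError(
                f"hydrogen atom {int(h)} has no donor within {max_dh} A "
                f"(nearest at {dmin:.3f} A)")
        pairing[int(h)] = int(d_idx[nearest[k]])
    return pairing


def detect_hbonds(config: Configuration,
                  criteria: Optional[HBondCriteria] = None) -> HBondSet:
    """All D-H...A triples satisfying the geometric criteria.

    Hydrogens are first paired covalently to their nearest donor; every
    (paired hydrogen, acceptor) combination is then screened.  The acceptor
    may not be the hydrogen's own donor.
    """
    criteria = criteria or HBondCriteria()
    roles = config.hbond_roles
    if roles is None:
        raise GelKineticsError("configuration carries no hydrogen-bond role annotations")
    box = config.box_edge
    pairing = pair_hydrogens_to_donors(config, criteria.max_dh)
    a_idx = np.flatnonzero(roles == "acceptor")
    bonds = []
    for h, d in pairing.items():
        pd, ph = config.positions[d], config.positions[h]
        for a in a_idx:
            if int(a) == d:
                continue
            d_da, d_ha, dev = _hbond_geometry(pd, ph, config.positions[a], box)
            if (d_da <= criteria.max_da + _EPS
                    and d_ha < criteria.max_ha - _EPS
                    and dev <= criteria.max_angle_dev + _EPS):
                bonds.append(HBond(d, h, int(a), d_da, d_ha, dev))
    result = HBondSet(bonds=bonds, criteria=criteria)
    try:
        classes = classify_sites(config)
    except GelKineticsError:
        classes = None
    if classes is not None:
        for b in result.bonds:
            result.donor_class_counts[classes[b.donor]] = \
                result.donor_class_counts.get(classes[b.donor], 0) + 1
            result.acceptor_class_counts[classes[b.acceptor]] = \
                result.acceptor_class_counts.get(classes[b.acceptor], 0) + 1
    return result


#: Site tags used by the generators and input files, mapped to chemical
#: site classes of the studied polymers (HEMA carbonyl/ether/hydroxyl
#: oxygens, VP carbonyl oxygen and ring nitrogen, water).
SITE_CLASSES: dict[str, str] = {
    "O_H1": "carbonyl O (HEMA)",
    "O_H2": "ether O (HEMA)",
    "O_H3": "hydroxyl O (HEMA)",
    "H_O3": "hydroxyl H (HEMA)",
    "O_V": "carbonyl O (VP)",
    "N_V": "ring N (VP)",
    "O_W": "water O",
    "H_W": "water H",
}


def classify_sites(config: Configuration,
                   site_map: Optional[dict[str, str]] = None) -> np.ndarray:
    """Per-atom site classes from label tags; unknown tags raise.

    Extra tags can be supplied via ``site_map`` (merged over the default
    registry).
    """
    table = dict(SITE_CLASSES)
    if site_map:
        table.update(site_map)
    classes = []
    for i, lab in enumerate(config.labels):
        if lab not in table:
            raise GelKineticsError(f"unknown site tag {lab!r} for atom {i}")
        classes.append(table[lab])
    return np.asarray(classes, dtype=object)


def site_class_counts(config: Configuration,
                      site_map: Optional[dict[str, str]] = None) -> dict[str, int]:
    classes = classify_sites(config, site_map)
    out: dict[str, int] = {}
    for c in classes:
        out[c] = out.get(c, 0) + 1
    return out


# ---------------------------------------------------------------------------
# free volume

@dataclass
class FreeVolumeResult:
    probe_radius: float  # A
    grid_spacing: float  # A (actual, after fitting the box)
    ffv: float  # percent
    free_voxel_count: int
    total_voxel_count: int
    channel_labels: np.ndarray  # (m, m, m) int; 0 = occupied
    channel_volumes: np.ndarray  # A^3, descending

    @property
    def n_channels(self) -> int:
        return len(self.channel_volumes)


def _periodic_merge(labels: np.ndarray) -> np.ndarray:
    """Merge connected-component labels across periodic faces (union-find)."""
    nlab = labels.max()
    if nlab == 0:
        return labels
    parent = np.arange(nlab + 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for axis in range(3):
        lo = np.take(labels, 0, axis=axis).ravel()
        hi = np.take(labels, -1, axis=axis).ravel()
        for a, b in zip(lo, hi):
            if a and b:
                union(a, b)
    roots = np.array([find(i) for i in range(nlab + 1)])
    # compact numbering
    uniq = np.unique(roots[1:])
    remap = np.zeros(nlab + 1, dtype=labels.dtype)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    return remap[roots][labels]


def free_volume(config: Configuration, probe_radius: float = 0.0,
                grid_spacing: float = 0.25) -> FreeVolumeResult:
    """Voxel-grid free volume with a spherical probe.

    A voxel center is free when farther than (vdW radius + probe radius)
    from every atom under minimum image.  FFV is reported in percent;
    channels are periodic 6-connected components of the free voxels.
    A probe radius of 0 is the point-probe limit.
    """
    box = config.require_box()
    if probe_radius < 0:
        raise GelKineticsError("probe_radius must be >= 0")
    limit = probe_radius / 2.0 if probe_radius > 0 else 0.5
    if grid_spacing > limit + 1e-12:
        raise GelKineticsError(
            f"grid too coarse: spacing {grid_spacing} A exceeds "
            f"{'probe_radius/2' if probe_radius > 0 else '0.5 A (point probe)'}")
    if config.n_atoms > 0 and config.vdw_radii is None:
        raise GelKineticsError("free_volume needs per-atom vdW radii (set elements or vdw_radii)")
    m = max(int(math.ceil(box / grid_spacing)), 2)
    h = box / m
    occupied = np.zeros((m, m, m), dtype=bool)
    for i in range(config.n_atoms):
        R = config.vdw_radii[i] + probe_radius
        if R <= 0:
            continue
        p = config.positions[i]
        lo = np.floor((p - R) / h - 0.5).astype(int)
        hi = np.ceil((p + R) / h - 0.5).astype(int) + 1
        # clip the stencil so periodic index folding never duplicates voxels
        ranges = []
        for ax in range(3):
            if hi[ax] - lo[ax] >= m:
                ranges.append(np.arange(m))
            else:
                ranges.append(np.arange(lo[ax], hi[ax]))
        ix, iy, iz = ranges
        cx = (ix + 0.5) * h - p[0]
        cy = (iy + 0.5) * h - p[1]
        cz = (iz + 0.5) * h - p[2]
        d2 = (_min_image(cx, box)[:, None, None] ** 2
              + _min_image(cy, box)[None, :, None] ** 2
              + _min_image(cz, box)[None, None, :] ** 2)
        inside = d2 <= R * R
        if not inside.any():
            continue
        sub = occupied[np.ix_(np.mod(ix, m), np.mod(iy, m), np.mod(iz, m))]
        occupied[np.ix_(np.mod(ix, m), np.mod(iy, m), np.mod(iz, m))] = sub | inside
    free = ~occupied
    n_free = int(free.sum())
    total = m ** 3
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, _ = ndimage.label(free, structure=struct)
    labels = _periodic_merge(labels)
    if labels.max() > 0:
        counts = np.bincount(labels.ravel())[1:]
        vols = np.sort(counts[counts > 0])[::-1] * h ** 3
    else:
        vols = np.empty(0)
    return FreeVolumeResult(probe_radius=probe_radius, grid_spacing=h,
                            ffv=100.0 * n_free / total, free_voxel_count=n_free,
                            total_voxel_count=total, channel_labels=labels,
                            channel_volumes=vols)


def strip_selection(config: Configuration, selection: Selection) -> Configuration:
    """Remove the selected atoms, keeping the (swollen) box unchanged.

    An empty selection is the identity (nothing removed)."""
    idx = resolve_selection(config.labels, selection, allow_empty=True)
    keep = np.setdiff1d(np.arange(config.n_atoms), idx)
    if len(keep) == 0:
        raise GelKineticsError("strip_selection would leave an empty configuration")

    def take(arr):
        return arr[keep] if arr is not None else None

    return Configuration(
        positions=config.positions[keep],
        box_edge=config.box_edge,
        labels=take(config.labels),
        elements=take(config.elements),
        vdw_radii=take(config.vdw_radii),
        hbond_roles=take(config.hbond_roles),
    )
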
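"""Hot-spot occupancy, pocket definition, energy envelopes and pocket volumes.

Three complementary site-detection routes are implemented over a conformer
ensemble:

* fragment-probe aggregation — count heavy-atom contacts (< 5.0 Å) between
  probe poses and protein residues, normalise across the ensemble, and group
  hot residues spatially into named pockets;
* grid route — a Lennard-Jones affinity grid around the protein, searched
  for the contiguous envelope of the most favourable grid points (default
  70, one point per prospective ligand atom centre);
* volumetry — per-conformer pocket volume as inclusion-sphere lattice points
  that do not clash with protein atoms, keeping the largest connected void.
"""

from __future__ import annotations

import heapq
import itertools
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ValidationError
from .structure_io import ResidueId, Structure, as_residue_id

__all__ = [
    "ProbePose",
    "OccupancyProfile",
    "Pocket",
    "AffinityGrid",
    "GridEnvelope",
    "BONDI_RADII",
    "vdw_radius",
    "probe_contact_residues",
    "ensemble_occupancy",
    "define_pockets",
    "build_affinity_grid",
    "find_envelope",
    "pocket_volume",
    "write_opendx",
]

#: Bondi van der Waals radii (Å) by element
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "MG": 1.73, "ZN": 1.39, "NA": 2.27, "K": 2.75,
}


def vdw_radius(element: str) -> float:
    r = BONDI_RADII.get(element.upper())
    if r is None:
        warnings.warn(f"unknown element {element!r}; using 1.7 Å van der Waals radius")
        return 1.7
    return r


@dataclass
class ProbePose:
    """One placed fragment probe (heavy atoms only)."""

    probe_id: str
    elements: list[str]
    coords: np.ndarray
    source_conformer: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.coords.shape[0] < 1:
            raise ValidationError(f"probe {self.probe_id}: no heavy atoms")
        if len(self.elements) != self.coords.shape[0]:
            raise ValidationError(f"probe {self.probe_id}: element/coordinate mismatch")
        if any(e.upper() in ("H", "D") for e in self.elements):
            raise ValidationError(f"probe {self.probe_id}: hydrogens not allowed")


def probe_contact_residues(
    structure: Structure,
    pose,
    cutoff: float = 5.0,
) -> set[ResidueId]:
    """Polymer residues with any heavy atom strictly within ``cutoff`` of any
    probe heavy atom (the 5.0 Å fragment-contact rule)."""
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    coords = np.asarray(pose.coords, float).reshape(-1, 3)
    if coords.shape[0] == 0:
        raise ValidationError("pose has no heavy atoms")
    tree = cKDTree(coords)
    out: set[ResidueId] = set()
    for rid, idxs in structure.polymer_residues().items():
        heavy = [i for i in idxs if not structure.atoms[i].is_hydrogen]
        if not heavy:
            continue
        pts = np.array([structure.atoms[i].coord for i in heavy])
        d, _ = tree.query(pts, k=1)
        if float(np.min(d)) < cutoff:
            out.add(rid)
    return out


@dataclass
class OccupancyProfile:
    """Ensemble-normalised per-residue probe occupancy.

    ``raw_counts[r]`` is the number of (conformer, pose) pairs contacting
    residue r; ``values`` divide by the ensemble-wide maximum so the
    most-contacted residue scores 1.0.
    """

    values: dict[ResidueId, float]
    raw_counts: dict[ResidueId, int]
    n_conformers: int

    def to_rows(self) -> list[tuple[str, int, str, int, float]]:
        rows = []
        for rid in sorted(self.raw_counts, key=lambda r: (r.chain, r.resid, r.icode)):
            rows.append((rid.chain, rid.resid, rid.icode, self.raw_counts[rid], self.values[rid]))
        return rows


def ensemble_occupancy(
    contacts: Mapping[str, Sequence[Iterable]],
    normalization: str = "max",
) -> OccupancyProfile:
    """Aggregate per-pose contact residue sets into an occupancy profile.

    Parameters
    ----------
    contacts : mapping
        conformer id -> list of contact-residue sets (one per probe pose).
    normalization : {"max", "per_pose"}
        "max" divides raw counts by the ensemble-wide maximum count
        (default); "per_pose" divides by n_conformers × n_poses.
    """
    if not contacts:
        raise ValidationError("need at least one conformer")
    raw: dict[ResidueId, int] = {}
    n_pairs = 0
    for _conf, pose_sets in contacts.items():
        for residue_set in pose_sets:
            n_pairs += 1
            for rid in residue_set:
                rid = as_residue_id(rid)
                raw[rid] = raw.get(rid, 0) + 1
    if normalization == "max":
        denom = max(raw.values()) if raw else 1
    elif normalization == "per_pose":
        denom = max(n_pairs, 1)
    else:
        raise ValidationError(f"unknown normalization {normalization!r}")
    values = {rid: c / denom for rid, c in raw.items()}
    return OccupancyProfile(values=values, raw_counts=raw, n_conformers=len(contacts))


@dataclass
class Pocket:
    """A named candidate binding site: a residue set with ensemble statistics."""

    pocket_id: str
    residues: frozenset[ResidueId]
    accessible_in: frozenset[str] = frozenset()
    volume_mean: float | None = None
    volume_sd: float | None = None
    is_active_site: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"pocket {self.pocket_id}: empty residue set")
        self.residues = frozenset(as_residue_id(r) for r in self.residues)
        self.accessible_in = frozenset(self.accessible_in)

    def to_dict(self) -> dict:
        return {
            "pocket_id": self.pocket_id,
            "residues": sorted([list(r) for r in self.residues]),
            "accessible_in": sorted(self.accessible_in),
            "volume_mean": self.volume_mean,
            "volume_sd": self.volume_sd,
            "is_active_site": self.is_active_site,
        }


def define_pockets(
    profile: OccupancyProfile,
    structure: Structure,
    occupancy_floor: float = 0.25,
    link_distance: float = 8.0,
    nucleotide_contact_residues: Iterable | None = None,
) -> list[Pocket]:
    """Partition hot-spot residues into spatially contiguous pockets.

    Residues with occupancy >= ``occupancy_floor`` are single-linkage
    clustered on Cα positions at ``link_distance`` Å.  Pockets are labelled
    p1, p2, ... by descending mean occupancy.  Residues belonging to the
    nucleotide-contact set (if given) are segregated into an "active-site"
    pocket labelled "nuc".
    """
    if not (0.0 < occupancy_floor <= 1.0):
        raise ValidationError(f"occupancy_floor must be in (0,1], got {occupancy_floor}")
    nuc = {as_residue_id(r) for r in (nucleotide_contact_residues or ())}
    hot = [rid for rid, v in profile.values.items() if v >= occupancy_floor]
    if not hot:
        return []
    ca = structure.calpha_index()
    placeable = [rid for rid in hot if rid in ca]
    missing = set(hot) - set(placeable)
    if missing:
        warnings.warn(f"{len(missing)} hot residues lack C-alpha in structure; skipped")
    if not placeable:
        return []
    active = [rid for rid in placeable if rid in nuc]
    surface = [rid for rid in placeable if rid not in nuc]
    groups: list[list[ResidueId]] = []
    if surface:
        pts = np.array([structure.atoms[ca[r]].coord for r in surface])
        if len(surface) == 1:
            labels = np.zeros(1, dtype=int)
        else:
            from scipy.cluster.hierarchy import fcluster, linkage

            z = linkage(pts, method="single", metric="euclidean")
            labels = fcluster(z, t=link_distance, criterion="distance") - 1
        for lab in np.unique(labels):
            groups.append([surface[i] for i in np.nonzero(labels == lab)[0]])
    # order by descending mean occupancy; ties by lowest (chain,resid)
    def mean_occ(group):
        return float(np.mean([profile.values[r] for r in group]))

    groups.sort(key=lambda g: (-mean_occ(g), sorted(g)[0]))
    pockets = [
        Pocket(pocket_id=f"p{i + 1}", residues=frozenset(g)) for i, g in enumerate(groups)
    ]
    if active:
        pockets.append(
            Pocket(pocket_id="nuc", residues=frozenset(active), is_active_site=True)
        )
    return pockets


def pocket_accessibility(
    pockets: Sequence[Pocket],
    contacts: Mapping[str, Sequence[Iterable]],
) -> list[Pocket]:
    """Mark each pocket accessible in the conformers where any pose contacts it."""
    out = []
    for p in pockets:
        acc = set()
        for conf, pose_sets in contacts.items():
            for residue_set in pose_sets:
                if any(as_residue_id(r) in p.residues for r in residue_set):
                    acc.add(conf)
                    break
        out.append(
            Pocket(
                pocket_id=p.pocket_id,
                residues=p.residues,
                accessible_in=frozenset(acc),
                volume_mean=p.volume_mean,
                volume_sd=p.volume_sd,
                is_active_site=p.is_active_site,
            )
        )
    return out


def write_pockets_json(pockets: Sequence[Pocket], path) -> None:
    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in pockets], fh, indent=1, sort_keys=True)


def read_pockets_json(path) -> list[Pocket]:
    with open(path) as fh:
        raw = json.load(fh)
    return [
        Pocket(
            pocket_id=d["pocket_id"],
            residues=frozenset(as_residue_id(tuple(r)) for r in d["residues"]),
            accessible_in=frozenset(d.get("accessible_in", ())),
            volume_mean=d.get("volume_mean"),
            volume_sd=d.get("volume_sd"),
            is_active_site=d.get("is_active_site", False),
        )
        for d in raw
    ]


# ---------------------------------------------------------------------------
# affinity grid + envelope search
# ---------------------------------------------------------------------------


@dataclass
class AffinityGrid:
    """Regular grid of probe interaction energies (lower = more favourable).

    Points inside a hard clash with the protein carry +inf and never enter
    envelope searches.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray  # (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValidationError("grid values must be 3-D and non-empty")
        if self.spacing <= 0:
            raise ValidationError("grid spacing must be positive")
        if np.any(np.isnan(self.values)):
            raise ValidationError("grid contains NaN")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def point_coords(self, idx) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(idx, dtype=float)


def build_affinity_grid(
    structure: Structure,
    spacing: float = 0.375,
    padding: float = 4.0,
    epsilon: float = 0.2,
    sigma: float = 3.4,
    clash_distance: float = 2.0,
    d_min: float = 0.5,
) -> AffinityGrid:
    """Single-probe Lennard-Jones affinity grid over the protein bounding box.

    Each grid point gets Σ_atoms 4ε[(σ/d)¹² − (σ/d)⁶] over protein heavy
    atoms, with d clamped to >= ``d_min``; points within ``clash_distance``
    of any heavy atom are marked +inf (sterically excluded).
    """
    if spacing <= 0:
        raise ValidationError("spacing must be positive")
    heavy = structure.heavy_indices()
    if heavy.size == 0:
        raise ValidationError("structure has no heavy atoms")
    atom_xyz = structure.coords[heavy]
    lo = atom_xyz.min(axis=0) - padding
    hi = atom_xyz.max(axis=0) + padding
    dims = np.maximum(np.floor((hi - lo) / spacing).astype(int) + 1, 1)
    axes = [lo[d] + spacing * np.arange(dims[d]) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    values = np.zeros(len(pts))
    clash = np.zeros(len(pts), dtype=bool)
    # chunked accumulation keeps memory bounded for larger systems
    chunk = max(1, int(2e7 // max(len(atom_xyz), 1)))
    for start in range(0, len(pts), chunk):
        block = pts[start : start + chunk]
        d = np.linalg.norm(block[:, None, :] - atom_xyz[None, :, :], axis=2)
        clash[start : start + chunk] = np.any(d < clash_distance, axis=1)
        d = np.clip(d, d_min, None)
        sr6 = (sigma / d) ** 6
        values[start : start + chunk] = np.sum(4.0 * epsilon * (sr6 * sr6 - sr6), axis=1)
    values[clash] = np.inf
    return AffinityGrid(origin=lo, spacing=spacing, values=values.reshape(tuple(dims)))


@dataclass
class GridEnvelope:
    """A contiguous (26-connected) set of favourable grid points."""

    points: frozenset[tuple[int, int, int]]
    total_energy: float
    contiguous: bool = True

    def __post_init__(self) -> None:
        self.points = frozenset(tuple(int(c) for c in p) for p in self.points)
        if len(self.points) > 1 and not _is_connected(self.points):
            raise ValidationError("envelope points are not 26-connected")


_NEIGHBOR_OFFSETS = [
    off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
]


def _is_connected(points: frozenset) -> bool:
    pts = set(points)
    start = next(iter(pts))
    seen = {start}
    stack = [start]
    while stack:
        p = stack.pop()
        for off in _NEIGHBOR_OFFSETS:
            q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
            if q in pts and q not in seen:
                seen.add(q)
                stack.append(q)
    return len(seen) == len(pts)


def find_envelope(
    grid: AffinityGrid,
    n_points: int = 70,
    n_seeds: int = 10,
) -> GridEnvelope:
    """Best contiguous envelope of ``n_points`` favourable grid points.

    Greedy growth with multi-seed restarts: from each of the ``n_seeds``
    lowest-energy finite points, repeatedly absorb the cheapest 26-neighbour
    of the current envelope until it holds ``n_points``; the envelope with
    the lowest total energy wins.  Deterministic tie-breaking by grid index.
    """
    if n_points < 1:
        raise ValidationError("n_points must be >= 1")
    vals = grid.values
    finite = np.isfinite(vals)
    if int(finite.sum()) < n_points:
        raise ValidationError(
            f"grid has {int(finite.sum())} finite points, need {n_points}"
        )
    flat_order = np.argsort(vals, axis=None, kind="stable")
    seeds = []
    for flat in flat_order:
        idx = np.unravel_index(flat, vals.shape)
        if np.isfinite(vals[idx]):
            seeds.append(tuple(int(c) for c in idx))
        if len(seeds) >= max(1, n_seeds):
            break

    shape = vals.shape
    best: tuple[float, frozenset] | None = None
    for seed in seeds:
        env = {seed}
        total = float(vals[seed])
        heap: list[tuple[float, tuple[int, int, int]]] = []
        in_heap = set()

        def push_neighbors(p):
            for off in _NEIGHBOR_OFFSETS:
                q = (p[0] + off[0], p[1] + off[1], p[2] + off[2])
                if (
                    0 <= q[0] < shape[0]
                    and 0 <= q[1] < shape[1]
                    and 0 <= q[2] < shape[2]
                    and q not in env
                    and q not in in_heap
                    and np.isfinite(vals[q])
                ):
                    heapq.heappush(heap, (float(vals[q]), q))
                    in_heap.add(q)

        push_neighbors(seed)
        while len(env) < n_points and heap:
            e, q = heapq.heappop(heap)
            in_heap.discard(q)
            if q in env:
                continue
            env.add(q)
            total += e
            push_neighbors(q)
        if len(env) == n_points and (best is None or total < best[0] - 1e-12):
            best = (total, frozenset(env))
    if best is None:
        raise ValidationError("no seed produced a full-size envelope")
    return GridEnvelope(points=best[1], total_energy=best[0])


def write_opendx(grid: AffinityGrid, path) -> None:
    """Serialise a grid as OpenDX scalar-field text for visualisation."""
    nx, ny, nz = grid.dims
    v = np.where(np.isfinite(grid.values), grid.values, 9999.0).ravel()
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.4f} {:.4f} {:.4f}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing:.4f} 0 0\ndelta 0 {grid.spacing:.4f} 0\n")
        fh.write(f"delta 0 0 {grid.spacing:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(f"object 3 class array type double rank 0 items {v.size} data follows\n")
        for start in range(0, v.size, 3):
            fh.write(" ".join(f"{x:.6g}" for x in v[start : start + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


# ---------------------------------------------------------------------------
# pocket volumetry
# ---------------------------------------------------------------------------


def _sphere_lattice(center: np.ndarray, radius: float, spacing: float) -> np.ndarray:
    """Lattice points (center + spacing·Z³) within ``radius`` of the center."""
    n = int(np.floor(radius / spacing))
    rng = spacing * np.arange(-n, n + 1)
    gx, gy, gz = np.meshgrid(rng, rng, rng, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    keep = np.sum(pts**2, axis=1) <= radius**2 + 1e-9
    return center + pts[keep]


def _largest_component_count(kept_pts: np.ndarray, center: np.ndarray, spacing: float, radius: float) -> int:
    """Count of points in the largest 26-connected component of the kept set."""
    if kept_pts.shape[0] == 0:
        return 0
    n = int(np.floor(radius / spacing))
    size = 2 * n + 1
    occ = np.zeros((size, size, size), dtype=bool)
    idx = np.rint((kept_pts - center) / spacing).astype(int) + n
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    labels, n_lab = ndimage.label(occ, structure=np.ones((3, 3, 3), dtype=int))
    if n_lab == 0:
        return 0
    counts = np.bincount(labels.ravel())[1:]
    return int(counts.max())


def pocket_volume(
    structures: Sequence[Structure],
    pocket: Pocket,
    spacing: float = 1.0,
    inclusion_radius: float = 8.0,
    exclusion_pad: float = 1.09,
    center: np.ndarray | None = None,
) -> tuple[np.ndarray, float, float]:
    """Per-conformer pocket volume with ensemble mean and SD (Å³).

    For each (core-aligned) conformer: lattice points inside the inclusion
    sphere centred at the pocket-residue Cα centroid (or an explicit
    ``center``), minus points within (Bondi vdW radius + ``exclusion_pad``)
    of any protein heavy atom, keeping only the largest 26-connected
    component of what remains.  Volume = point count × spacing³; the SD uses
    divisor N−1.
    """
    if spacing <= 0 or inclusion_radius <= 0:
        raise ValidationError("spacing and inclusion_radius must be positive")
    volumes = []
    for s in structures:
        ca = s.calpha_index()
        if center is None:
            anchors = [s.atoms[ca[r]].xyz for r in pocket.residues if r in ca]
            if not anchors:
                raise ValidationError(
                    f"structure {s.id}: no C-alpha found for pocket {pocket.pocket_id}"
                )
            c = np.mean(anchors, axis=0)
        else:
            c = np.asarray(center, dtype=float)
        pts = _sphere_lattice(c, inclusion_radius, spacing)
        if pts.shape[0] == 0:
            raise ValidationError("empty inclusion region")
        heavy = s.heavy_indices()
        if heavy.size:
            atom_xyz = s.coords[heavy]
            radii = np.array([vdw_radius(s.atoms[i].element) for i in heavy])
            tree = cKDTree(pts)
            excluded = np.zeros(len(pts), dtype=bool)
            for r in np.unique(radii):
                sub = atom_xyz[radii == r]
                hit = tree.query_ball_point(sub, r + exclusion_pad)
                for lst in hit:
                    excluded[lst] = True
            pts = pts[~excluded]
        count = _largest_component_count(pts, c, spacing, inclusion_radius)
        volumes.append(count * spacing**3)
    volumes = np.asarray(volumes, dtype=float)
    mean = float(volumes.mean())
    sd = float(volumes.std(ddof=1)) if len(volumes) > 1 else 0.0
    return volumes, mean, sd
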
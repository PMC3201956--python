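"""Conformer-ensemble construction, Cα PCA, clustering and representative selection.

The workflow mirrors the standard "relaxed complex" ensemble scheme:

1. collect equivalent Cα coordinates across conformers,
2. iteratively find the invariant core (positions with least scatter) and
   superpose every conformer onto it,
3. run PCA on the equivalent-Cα covariance matrix,
4. cluster conformers (average linkage on PC1–3 distances, or on pairwise
   RMSD) and pick, per cluster, the member closest to the cluster-average
   coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import (
    CoreFailureError,
    FitError,
    InsufficientDataError,
    ValidationError,
)
from .structure_io import ResidueId, Structure, as_residue_id

__all__ = [
    "ConformerEnsemble",
    "PCAModel",
    "ClusterResult",
    "superpose",
    "apply_transform",
    "find_invariant_core",
    "fit_pca",
    "pairwise_rmsd",
    "cluster_conformers",
    "select_representatives",
    "dihedral",
    "chi1_series",
]


# ---------------------------------------------------------------------------
# rigid-body superposition (Kabsch)
# ---------------------------------------------------------------------------


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    fit_indices: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits the reference over
    ``fit_indices`` (all points by default).  The rotation is proper
    (det = +1).  RMSD is computed over the fit points after the transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise FitError(f"shape mismatch: {mobile.shape} vs {reference.shape}")
    idx = np.arange(len(mobile)) if fit_indices is None else np.asarray(fit_indices, int)
    if len(idx) < 3:
        raise FitError(f"need >=3 fit points, got {len(idx)}")
    x = mobile[idx]
    y = reference[idx]
    xc = x.mean(axis=0)
    yc = y.mean(axis=0)
    x0 = x - xc
    y0 = y - yc
    # degenerate (collinear) geometry has covariance rank < 2
    h = x0.T @ y0
    u, s, vt = np.linalg.svd(h)
    if np.sum(s > 1e-10 * max(s[0], 1e-30)) < 2:
        raise FitError("degenerate (collinear) fit geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = yc - rotation @ xc
    moved = x @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - y) ** 2, axis=1))))
    return rotation, translation, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords, float) @ np.asarray(rotation).T + np.asarray(translation)


def coord_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain RMSD between already-aligned coordinate sets."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# ensemble container
# ---------------------------------------------------------------------------


@dataclass
class ConformerEnsemble:
    """Aligned equivalent-Cα coordinates for a set of conformers.

    ``coords`` has shape (n_conformers, n_equiv, 3) and is kept superposed on
    the current ``core`` (all positions until :func:`find_invariant_core` is
    applied).  ``equiv_map`` records, per structure, which residue supplied
    each shared position.
    """

    structures: list[Structure]
    coords: np.ndarray
    equiv_map: list[dict[int, ResidueId]]
    core: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError("coords must be (n_conformers, n_equiv, 3)")
        if self.coords.shape[0] != len(self.structures):
            raise ValidationError("one coordinate row per structure required")
        if self.core is None:
            self.core = np.arange(self.coords.shape[1])
        self.core = np.asarray(self.core, dtype=int)

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    @property
    def n_equiv(self) -> int:
        return self.coords.shape[1]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.structures]

    @property
    def coords2d(self) -> np.ndarray:
        """(n_conformers, 3*n_equiv) flattened view."""
        return self.coords.reshape(self.n_conformers, -1)

    @classmethod
    def from_structures(
        cls,
        structures: Sequence[Structure],
        equiv_table: Mapping[str, Mapping[int, tuple]] | None = None,
    ) -> "ConformerEnsemble":
        """Build an ensemble from the Cα atoms shared by all structures.

        Without an explicit ``equiv_table`` (structure id -> shared index ->
        residue key), residues are matched by identical ``(chain, resid,
        icode)``; an explicit table is the supported route when author
        numbering differs between structures.
        """
        structures = list(structures)
        if not structures:
            raise ValidationError("empty structure list")
        ca_maps = [s.calpha_index() for s in structures]
        if equiv_table is None:
            shared = [rid for rid in ca_maps[0] if all(rid in m for m in ca_maps)]
            if not shared:
                raise ValidationError("no shared C-alpha residues across structures")
            equiv_map = [{i: rid for i, rid in enumerate(shared)} for _ in structures]
        else:
            n_shared = None
            equiv_map = []
            for s in structures:
                try:
                    table = equiv_table[s.id]
                except KeyError as exc:
                    raise ValidationError(f"equivalence table missing structure {s.id}") from exc
                mapping = {int(i): as_residue_id(k) for i, k in table.items()}
                if n_shared is None:
                    n_shared = len(mapping)
                elif len(mapping) != n_shared:
                    raise ValidationError("inconsistent equivalence table sizes")
                equiv_map.append(mapping)
        coords = []
        for s, camap, emap in zip(structures, ca_maps, equiv_map):
            row = []
            for i in range(len(emap)):
                rid = emap[i]
                if rid not in camap:
                    raise ValidationError(f"structure {s.id}: no C-alpha for {rid}")
                row.append(s.atoms[camap[rid]].coord)
            coords.append(row)
        ens = cls(structures=structures, coords=np.asarray(coords, float), equiv_map=equiv_map)
        ens.superpose_all()
        return ens

    def superpose_all(self, fit_indices: Sequence[int] | None = None, n_iter: int = 2) -> None:
        """Superpose every conformer onto the iteratively-refined mean.

        The first pass fits onto conformer 0, then ``n_iter`` passes fit onto
        the current mean (the usual progressive-mean alignment).
        """
        idx = self.core if fit_indices is None else np.asarray(fit_indices, int)
        ref = self.coords[0]
        for _ in range(max(1, n_iter)):
            aligned = []
            for row in self.coords:
                r, t, _ = superpose(row, ref, idx)
                aligned.append(apply_transform(row, r, t))
            self.coords = np.asarray(aligned)
            ref = self.coords.mean(axis=0)

    def residue_of(self, conformer: int, shared_index: int) -> ResidueId:
        return self.equiv_map[conformer][int(shared_index)]


# ---------------------------------------------------------------------------
# invariant core
# ---------------------------------------------------------------------------


def _position_ellipsoid_volumes(coords: np.ndarray) -> np.ndarray:
    """Per-position volume of the covariance ellipsoid of conformer scatter (Å³)."""
    n_conf, n_pos, _ = coords.shape
    centered = coords - coords.mean(axis=0, keepdims=True)
    vols = np.empty(n_pos)
    for j in range(n_pos):
        cov = centered[:, j, :].T @ centered[:, j, :] / max(n_conf - 1, 1)
        eig = np.clip(np.linalg.eigvalsh(cov), 0.0, None)
        vols[j] = 4.0 / 3.0 * np.pi * float(np.prod(np.sqrt(eig)))
    return vols


def find_invariant_core(
    ensemble: ConformerEnsemble,
    volume_threshold: float = 0.5,
    min_fraction: float = 0.30,
) -> np.ndarray:
    """Iterative invariant-core search.

    Repeatedly: superpose all conformers on the current candidate set,
    measure each position's scatter as the volume of its positional
    covariance ellipsoid, and drop the worst position — until every
    remaining position scatters below ``volume_threshold`` Å³ or only
    ``min_fraction`` of positions remain.  The ensemble is left superposed
    on the final core and ``ensemble.core`` is updated.
    """
    if ensemble.n_conformers < 3:
        raise ValidationError("invariant-core search needs >=3 conformers")
    core = list(range(ensemble.n_equiv))
    floor = max(3, int(np.ceil(min_fraction * ensemble.n_equiv)))
    while True:
        ensemble.superpose_all(fit_indices=core)
        vols = _position_ellipsoid_volumes(ensemble.coords[:, core, :])
        worst = int(np.argmax(vols))
        if vols[worst] <= volume_threshold or len(core) <= floor:
            break
        core.pop(worst)
        if len(core) < 3:
            raise CoreFailureError("fewer than 3 positions survived core search")
    ensemble.core = np.asarray(sorted(core), dtype=int)
    ensemble.superpose_all()
    return ensemble.core


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """PCA of the equivalent-Cα covariance matrix.

    ``mean`` is the 3N-vector average conformation; eigenvector columns are
    orthonormal and sorted by descending eigenvalue (variances, Å²);
    ``projections`` are the scores of the fitted conformers.
    """

    mean: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    projections: np.ndarray

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    def project(self, coords2d: np.ndarray, k: int = 3) -> np.ndarray:
        """Scores of (already aligned) flattened conformations on the first k PCs."""
        coords2d = np.atleast_2d(np.asarray(coords2d, float))
        if coords2d.shape[1] != self.mean.shape[0]:
            raise ValidationError(
                f"dimension mismatch: {coords2d.shape[1]} vs model {self.mean.shape[0]}"
            )
        k = min(int(k), self.n_components)
        return (coords2d - self.mean) @ self.eigenvectors[:, :k]


def fit_pca(ensemble: ConformerEnsemble) -> PCAModel:
    """Diagonalise the covariance of equivalent-Cα coordinates (divisor N−1).

    Eigenvector signs follow the convention that each column's
    largest-magnitude component is positive.
    """
    n = ensemble.n_conformers
    if n < 2:
        raise InsufficientDataError("PCA needs at least 2 conformers")
    x = ensemble.coords2d
    mean = x.mean(axis=0)
    centered = x - mean
    cov = centered.T @ centered / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(evecs.shape[1]):
        i = int(np.argmax(np.abs(evecs[:, j])))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    projections = centered @ evecs
    return PCAModel(mean=mean, eigenvectors=evecs, eigenvalues=evals, projections=projections)


def project(
    coords: np.ndarray,
    model: PCAModel,
    k: int = 3,
) -> np.ndarray:
    """Convenience wrapper: project flattened, aligned conformations on PCs 1..k."""
    return model.project(coords, k=k)


# ---------------------------------------------------------------------------
# pairwise RMSD & clustering
# ---------------------------------------------------------------------------


def pairwise_rmsd(ensemble: ConformerEnsemble) -> np.ndarray:
    """Symmetric matrix of pairwise Cα RMSD after pairwise core superposition."""
    n = ensemble.n_conformers
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            _, _, r = superpose(ensemble.coords[j], ensemble.coords[i], ensemble.core)
            out[i, j] = out[j, i] = r
    return out


@dataclass
class ClusterResult:
    """Average-linkage clustering of conformers cut at k groups.

    ``labels`` are 0-based cluster indices renumbered by descending
    population (ties broken by lowest member index); ``linkage`` is the
    scipy merge tree.
    """

    linkage: np.ndarray
    labels: np.ndarray
    populations: list[int]
    representatives: dict[int, str] = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.populations)

    def members(self, label: int) -> np.ndarray:
        return np.nonzero(self.labels == label)[0]


def cluster_conformers(
    data: np.ndarray,
    k: int,
    metric: str = "auto",
) -> ClusterResult:
    """UPGMA (average-linkage) clustering cut to exactly k clusters.

    ``data`` is either a square symmetric distance matrix (zero diagonal) or
    an (n_conformers, m) score matrix — e.g. PC1–3 projections — in which
    case Euclidean distances are used.  ``metric`` forces the interpretation
    ("distance" | "scores"); "auto" treats square-symmetric-zero-diagonal
    input as distances.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValidationError("data must be 2-D")
    n = data.shape[0]
    if not (1 <= k <= n):
        raise ValidationError(f"k={k} out of range for {n} conformers")
    is_dist = metric == "distance" or (
        metric == "auto"
        and data.shape[0] == data.shape[1]
        and np.allclose(data, data.T, atol=1e-8)
        and np.allclose(np.diag(data), 0.0, atol=1e-8)
    )
    if is_dist:
        condensed = squareform(data, checks=False)
        z = linkage(condensed, method="average")
    else:
        z = linkage(data, method="average", metric="euclidean")
    raw = fcluster(z, t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        # maxclust can undershoot on exact ties; fall back to distance cut
        heights = np.sort(z[:, 2])
        for h in np.concatenate(([0.0], heights)):
            raw = fcluster(z, t=h, criterion="distance")
            if len(np.unique(raw)) == k:
                break
        else:
            raise ValidationError(f"cannot cut tree into exactly {k} clusters")
    # renumber by descending population, ties by lowest member index
    labels_raw = np.asarray(raw)
    info = []
    for lab in np.unique(labels_raw):
        members = np.nonzero(labels_raw == lab)[0]
        info.append((-len(members), members[0], lab))
    info.sort()
    remap = {old: new for new, (_, _, old) in enumerate(info)}
    labels = np.array([remap[l] for l in labels_raw], dtype=int)
    populations = [int(np.sum(labels == i)) for i in range(k)]
    return ClusterResult(linkage=z, labels=labels, populations=populations)


def select_representatives(
    ensemble: ConformerEnsemble,
    clusters: ClusterResult,
) -> dict[int, str]:
    """Per cluster, the member closest (RMSD) to the cluster-average coordinates.

    Ties break to the lowest conformer index.  Fills and returns
    ``clusters.representatives`` (cluster label -> structure id).
    """
    reps: dict[int, str] = {}
    for label in range(clusters.k):
        members = clusters.members(label)
        if members.size == 0:
            raise AssertionError(f"empty cluster {label}")
        mean = ensemble.coords[members].mean(axis=0)
        best, best_rmsd = None, np.inf
        for m in members:
            r = coord_rmsd(ensemble.coords[m], mean)
            if r < best_rmsd - 1e-12:
                best, best_rmsd = int(m), r
        reps[label] = ensemble.structures[best].id
    clusters.representatives = reps
    return reps


# ---------------------------------------------------------------------------
# side-chain dihedrals
# ---------------------------------------------------------------------------


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (−180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    # IUPAC sign: positive clockwise looking down the central bond
    ang = -np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def chi1_series(
    structures: Iterable[Structure],
    chain: str,
    resid: int,
    icode: str = "",
    bin_width: float = 10.0,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """χ1 (N–CA–CB–CG) angles of one residue across conformers, plus histogram density.

    Conformers missing any of the four atoms contribute NaN with a warning.
    The density is a normalised histogram over (−180, 180] with the given
    bin width (degrees).
    """
    rid = ResidueId(chain, resid, icode)
    angles = []
    for s in structures:
        res_atoms = {s.atoms[i].name: s.atoms[i].xyz for i in s.residues().get(rid, [])}
        # CG naming varies by residue type (CG, CG1, OG, OG1, SG ...)
        gamma = None
        for name in ("CG", "CG1", "OG", "OG1", "SG", "CG2"):
            if name in res_atoms:
                gamma = res_atoms[name]
                break
        if gamma is None or any(n not in res_atoms for n in ("N", "CA", "CB")):
            warnings.warn(f"structure {s.id}: residue {rid} missing chi1 atoms; NaN")
            angles.append(np.nan)
            continue
        angles.append(dihedral(res_atoms["N"], res_atoms["CA"], res_atoms["CB"], gamma))
    angles = np.asarray(angles, dtype=float)
    edges = np.arange(-180.0, 180.0 + bin_width, bin_width)
    finite = angles[np.isfinite(angles)]
    density, _ = np.histogram(finite, bins=edges, density=True) if finite.size else (
        np.zeros(len(edges) - 1),
        edges,
    )
    return angles, (edges, np.asarray(density, float))
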
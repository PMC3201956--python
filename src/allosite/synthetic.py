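"""Seeded synthetic fixtures with the statistical structure the pipeline assumes.

Generators emulate, at toy scale, the inputs each stage consumes: conformer
ensembles with planted collective modes plus isotropic noise, fragment-probe
poses concentrated at planted surface pockets, blind-dock pose sets with a
controllable site-preference matrix, and compound × scoring-function tables
with controllable inter-function rank agreement.  Every generator is a pure
function of its arguments including an explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .dock_analysis import LigandPose
from .consensus_screen import ScoreTable
from .ensemble_analysis import ConformerEnsemble
from .errors import ValidationError
from .pocket_mapping import Pocket, ProbePose
from .structure_io import Atom, ResidueId, Structure

__all__ = [
    "ToyEnsembleSpec",
    "clustered_ensemble_spec",
    "make_toy_ensemble",
    "make_probe_poses",
    "make_dock_poses",
    "make_score_table",
]


@dataclass
class ToyEnsembleSpec:
    """Recipe for a synthetic conformer ensemble.

    Each planted mode is a (3N displacement vector, per-conformer amplitude
    array) pair; conformer c is backbone + Σ amplitude_c·mode + N(0, noise_sd).
    ``planted_labels`` carries ground-truth cluster labels when the amplitude
    schedule was built from discrete groups.
    """

    n_residues: int
    n_conformers: int
    planted_modes: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    noise_sd: float = 0.0
    planted_pockets: list[tuple[tuple[int, ...], float]] = field(default_factory=list)
    seed: int = 0
    planted_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.seed is None:
            raise ValidationError("seed is mandatory")
        norm_modes = []
        for vec, amps in self.planted_modes:
            vec = np.asarray(vec, float).reshape(-1)
            amps = np.asarray(amps, float).reshape(-1)
            if vec.shape[0] != 3 * self.n_residues:
                raise ValidationError("mode vector must have length 3*n_residues")
            if amps.shape[0] != self.n_conformers:
                raise ValidationError("one amplitude per conformer required")
            if not (np.all(np.isfinite(vec)) and np.all(np.isfinite(amps))):
                raise ValidationError("mode vectors/amplitudes must be finite")
            norm_modes.append((vec, amps))
        self.planted_modes = norm_modes


def _helix_backbone(n_residues: int) -> np.ndarray:
    """Cα positions on an idealised helix (self-avoiding, ~3.8 Å neighbours)."""
    t = np.arange(n_residues)
    theta = t * (2 * np.pi / 3.6)  # 3.6 residues per turn
    r = 2.3
    z = t * 1.5
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts


def clustered_ensemble_spec(
    n_residues: int,
    cluster_sizes: Sequence[int],
    separation: float = 5.0,
    within_spread: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ToyEnsembleSpec:
    """Spec with one collective mode whose amplitudes form separated groups.

    Cluster centres sit at 0, ``separation``, 2·``separation``, … along the
    mode; members jitter by ``within_spread``.  Ground-truth labels ride in
    ``planted_labels``.
    """
    rng = np.random.default_rng(seed)
    n_conf = int(sum(cluster_sizes))
    mode = np.zeros(3 * n_residues)
    # displace the C-terminal third along x, a collective "lobe" motion
    for i in range(2 * n_residues // 3, n_residues):
        mode[3 * i] = 1.0
    mode /= np.linalg.norm(mode)
    amps = []
    labels = []
    for g, size in enumerate(cluster_sizes):
        centre = g * separation
        amps.extend(centre + within_spread * rng.standard_normal(size))
        labels.extend([g] * size)
    return ToyEnsembleSpec(
        n_residues=n_residues,
        n_conformers=n_conf,
        planted_modes=[(mode, np.asarray(amps))],
        noise_sd=noise_sd,
        seed=seed,
        planted_labels=np.asarray(labels, dtype=int),
    )


def make_toy_ensemble(spec: ToyEnsembleSpec) -> tuple[ConformerEnsemble, dict]:
    """Generate the ensemble plus ground truth (mode vectors, labels).

    The backbone is a geometric helix, one Cα atom per residue.  Structures
    are regenerated with fresh jitter (up to 100 attempts) if any two atoms
    land closer than 1.0 Å.
    """
    rng = np.random.default_rng(spec.seed)
    base = _helix_backbone(spec.n_residues)
    structures = []
    rows = []
    for c in range(spec.n_conformers):
        for attempt in range(100):
            coords = base.copy()
            for vec, amps in spec.planted_modes:
                coords = coords + amps[c] * vec.reshape(-1, 3)
            if spec.noise_sd > 0:
                coords = coords + rng.normal(0.0, spec.noise_sd, size=coords.shape)
            from scipy.spatial.distance import pdist

            if spec.n_residues < 2 or float(pdist(coords).min()) >= 1.0:
                break
            coords = None  # retry with fresh noise
        else:
            raise ValidationError("could not place non-overlapping atoms in 100 tries")
        atoms = [
            Atom(
                serial=i + 1,
                name="CA",
                element="C",
                resname="ALA",
                resid=i + 1,
                chain="A",
                coord=tuple(coords[i]),
            )
            for i in range(spec.n_residues)
        ]
        structures.append(Structure(id=f"conf{c:03d}", atoms=atoms))
        rows.append(coords)
    ensemble = ConformerEnsemble.from_structures(structures)
    truth = {
        "mode_vectors": [vec.copy() for vec, _ in spec.planted_modes],
        "amplitudes": [amps.copy() for _, amps in spec.planted_modes],
        "labels": None if spec.planted_labels is None else spec.planted_labels.copy(),
        "planted_pockets": list(spec.planted_pockets),
        "raw_coords": np.asarray(rows),
    }
    return ensemble, truth


def _surface_shell_point(coords: np.ndarray, rng, offset: float = 6.0) -> np.ndarray:
    """A random point on a shell just outside the molecular extent."""
    centre = coords.mean(axis=0)
    radius = float(np.max(np.linalg.norm(coords - centre, axis=1))) + offset
    v = rng.standard_normal(3)
    v /= np.linalg.norm(v)
    return centre + radius * v


def make_probe_poses(
    ensemble: ConformerEnsemble,
    planted_pockets: Sequence[Sequence[int]],
    n_poses: int = 20,
    hit_fraction: float = 0.8,
    seed: int = 0,
) -> dict[str, list[ProbePose]]:
    """Fragment-probe poses per conformer, concentrated at planted pockets.

    ``planted_pockets`` lists residue-index groups (0-based into the shared
    set).  A ``hit_fraction`` of poses lands within 4 Å of a planted pocket's
    residue centroid; the rest scatter on a surface shell.
    """
    if not (0.0 <= hit_fraction <= 1.0):
        raise ValidationError("hit_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    out: dict[str, list[ProbePose]] = {}
    for ci, s in enumerate(ensemble.structures):
        coords = ensemble.coords[ci]
        poses = []
        n_hits = int(round(hit_fraction * n_poses))
        for p in range(n_poses):
            if p < n_hits and planted_pockets:
                pocket = planted_pockets[rng.integers(len(planted_pockets))]
                centroid = coords[np.asarray(pocket, int)].mean(axis=0)
                centre = centroid + rng.normal(0.0, 4.0 / 3.0, size=3)
                # keep within the 4 Å placement envelope
                delta = centre - centroid
                norm = np.linalg.norm(delta)
                if norm > 3.5:
                    centre = centroid + delta * (3.5 / norm)
            else:
                centre = _surface_shell_point(coords, rng)
            probe_coords = centre + 0.7 * rng.standard_normal((3, 3))
            poses.append(
                ProbePose(
                    probe_id=f"{s.id}-probe{p:03d}",
                    elements=["C", "C", "O"],
                    coords=probe_coords,
                    source_conformer=s.id,
                )
            )
        out[s.id] = poses
    return out


def make_dock_poses(
    structure: Structure,
    pockets: Sequence[Pocket],
    preference: np.ndarray,
    n_compounds: int = 20,
    n_poses: int = 10,
    ki_range: tuple[float, float] = (1e-9, 1e-4),
    seed: int = 0,
) -> tuple[dict[str, list[LigandPose]], dict[str, list[str]]]:
    """Blind-dock pose sets with a controllable site-preference matrix.

    ``preference`` is either one row (shared by all compounds) or one row
    per compound over [pockets..., unassigned]; rows must sum to 1.  Poses
    for a drawn pocket are placed at that pocket's residue centroid;
    "unassigned" poses go to a far surface shell.  Ki is log-uniform over
    ``ki_range``.  Returns (poses by compound, true site draw by compound).
    """
    preference = np.atleast_2d(np.asarray(preference, dtype=float))
    n_sites = len(pockets) + 1
    if preference.shape[1] != n_sites:
        raise ValidationError(
            f"preference rows must have {n_sites} entries (pockets + unassigned)"
        )
    if not np.allclose(preference.sum(axis=1), 1.0, atol=1e-9):
        raise ValidationError("preference rows must sum to 1")
    if preference.shape[0] == 1:
        preference = np.repeat(preference, n_compounds, axis=0)
    if preference.shape[0] != n_compounds:
        raise ValidationError("one preference row per compound required")

    rng = np.random.default_rng(seed)
    ca = structure.calpha_index()
    centroids = []
    for p in pockets:
        anchors = [structure.atoms[ca[r]].xyz for r in p.residues if r in ca]
        if not anchors:
            raise ValidationError(f"pocket {p.pocket_id} has no C-alpha anchors")
        centroids.append(np.mean(anchors, axis=0))
    site_labels = [p.pocket_id for p in pockets] + ["unassigned"]
    all_xyz = structure.coords

    poses: dict[str, list[LigandPose]] = {}
    truth: dict[str, list[str]] = {}
    log_lo, log_hi = np.log10(ki_range[0]), np.log10(ki_range[1])
    for c in range(n_compounds):
        cid = f"cmpd{c:04d}"
        plist = []
        tlist = []
        for pi in range(n_poses):
            site = int(rng.choice(n_sites, p=preference[c]))
            if site < len(pockets):
                centre = centroids[site] + rng.normal(0.0, 1.0, size=3)
            else:
                centre = _surface_shell_point(all_xyz, rng, offset=25.0)
            lig_coords = centre + 0.8 * rng.standard_normal((4, 3))
            ki = float(10 ** rng.uniform(log_lo, log_hi))
            # one polar N with an explicit H, one O acceptor
            h_xyz = lig_coords[0] + np.array([1.0, 0.0, 0.0])
            plist.append(
                LigandPose(
                    compound_id=cid,
                    pose_index=pi,
                    elements=["N", "C", "C", "O"],
                    coords=lig_coords,
                    donors=[(0, h_xyz)],
                    acceptors=[3],
                    predicted_ki=ki,
                )
            )
            tlist.append(site_labels[site])
        poses[cid] = plist
        truth[cid] = tlist
    return poses, truth


def make_score_table(
    n_compounds: int = 50,
    n_functions: int = 8,
    rank_agreement: float = 1.0,
    seed: int = 0,
    ensemble_tag: str = "",
) -> ScoreTable:
    """Score table whose columns share a latent ranking to degree ρ.

    Each function's score is ρ·latent + √(1−ρ²)·noise; ρ=1 makes all
    functions rank identically, ρ=0 makes them independent.  Orientation per
    function is randomised (and declared): "higher" columns are sign-flipped.
    """
    if not (0.0 <= rank_agreement <= 1.0):
        raise ValidationError("rank_agreement must be in [0,1]")
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n_compounds)
    compounds = [f"cmpd{c:04d}" for c in range(n_compounds)]
    functions = [f"fn{j}" for j in range(n_functions)]
    rho = rank_agreement
    data = {}
    orientation = {}
    for fn in functions:
        noise = rng.standard_normal(n_compounds)
        score = rho * latent + np.sqrt(max(0.0, 1.0 - rho**2)) * noise
        if rng.random() < 0.5:
            orientation[fn] = "lower"
            data[fn] = score
        else:
            orientation[fn] = "higher"
            data[fn] = -score
    import pandas as pd

    df = pd.DataFrame(data, index=pd.Index(compounds, name="compound_id"))
    return ScoreTable(scores=df, orientation=orientation, ensemble_tag=ensemble_tag)
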
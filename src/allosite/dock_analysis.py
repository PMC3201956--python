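"""Blind-docking aggregation: pose→site assignment, site preferences,
geometric interaction reports, and Ki-ranked consistency-filtered hit lists.

Docked poses are consumed as data (coordinates, optional predicted
inhibition constants); the docking engine itself is upstream of this
package.  The geometric rules are the standard ones: probe-style residue
contact at < 5.0 Å heavy–heavy, hydrogen bonds at donor–acceptor < 3.5 Å
with D–H···A angle in [150°, 180°], van der Waals contacts at C–C < 5.0 Å.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .consensus_screen import CompoundDescriptors, lipinski_filter
from .errors import ValidationError
from .pocket_mapping import Pocket, probe_contact_residues
from .structure_io import Structure

__all__ = [
    "LigandPose",
    "SitePreference",
    "InteractionReport",
    "assign_pose_site",
    "site_preference",
    "detect_hbonds",
    "detect_vdw_contacts",
    "rank_and_filter_binders",
]

UNASSIGNED = "unassigned"


@dataclass
class LigandPose:
    """One docked pose of a compound.

    ``donors`` pairs a donor heavy-atom index with the coordinate of its
    attached hydrogen; ``acceptors`` are heavy-atom indices.
    ``predicted_ki`` is molar.
    """

    compound_id: str
    pose_index: int
    elements: list[str]
    coords: np.ndarray
    donors: list[tuple[int, np.ndarray]] = field(default_factory=list)
    acceptors: list[int] = field(default_factory=list)
    predicted_ki: float | None = None
    energy: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if self.coords.shape[0] < 1:
            raise ValidationError(f"pose {self.compound_id}/{self.pose_index}: no heavy atoms")
        if len(self.elements) != self.coords.shape[0]:
            raise ValidationError("element/coordinate count mismatch")
        n = self.coords.shape[0]
        self.donors = [(int(i), np.asarray(h, float).reshape(3)) for i, h in self.donors]
        for i, _h in self.donors:
            if not (0 <= i < n):
                raise ValidationError(f"donor index {i} out of range")
        self.acceptors = [int(i) for i in self.acceptors]
        for i in self.acceptors:
            if not (0 <= i < n):
                raise ValidationError(f"acceptor index {i} out of range")


@dataclass
class SitePreference:
    """Compound-weighted site-targeting frequencies.

    ``weights[site]`` is the mean, over compounds, of the fraction of each
    compound's poses landing at that site; they sum to 1.
    """

    weights: dict[str, float]
    n_compounds: int

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if self.n_compounds > 0 and abs(total - 1.0) > 1e-9:
            raise ValidationError(f"site-preference weights sum to {total}, not 1")


@dataclass
class InteractionReport:
    hbonds: list[tuple[str, str, float, float]]
    vdw_contacts: list[tuple[str, str, float]]


def assign_pose_site(
    pose: LigandPose,
    structure: Structure,
    pockets: Sequence[Pocket],
    cutoff: float = 5.0,
    min_overlap: float = 0.3,
) -> str:
    """Assign a pose to the pocket holding the largest fraction of its contacts.

    The pose's contact residues (heavy–heavy < ``cutoff``) are intersected
    with each pocket's residue set; the pocket maximising
    ``|contacts ∩ pocket| / |contacts|`` wins if the fraction reaches
    ``min_overlap``; ties break by larger intersection, then by pocket list
    order.  Poses contacting nothing, or below the overlap floor, are
    ``"unassigned"``.
    """
    if not pockets:
        raise ValidationError("no pockets to assign against")
    contacts = probe_contact_residues(structure, pose, cutoff=cutoff)
    if not contacts:
        return UNASSIGNED
    best = None  # (overlap_fraction, intersection_size, -order)
    for order, p in enumerate(pockets):
        inter = len(contacts & p.residues)
        frac = inter / len(contacts)
        key = (frac, inter, -order)
        if best is None or key > best[0]:
            best = (key, p.pocket_id)
    (frac, _inter, _), pocket_id = best
    return pocket_id if frac >= min_overlap else UNASSIGNED


def site_preference(
    assignments: Mapping[str, Sequence[str]],
) -> SitePreference:
    """Compound-weighted site preference from per-compound pose assignments.

    ``assignments`` maps compound id -> the site label of each of its poses
    (``"unassigned"`` allowed).  Each compound contributes its per-site pose
    frequency; weights are the mean over compounds.
    """
    freqs = []
    sites: set[str] = set()
    for cid, labels in sorted(assignments.items()):
        if len(labels) == 0:
            warnings.warn(f"compound {cid} has no poses; excluded")
            continue
        f: dict[str, float] = {}
        for lab in labels:
            f[lab] = f.get(lab, 0.0) + 1.0 / len(labels)
        freqs.append(f)
        sites.update(f)
    if not freqs:
        return SitePreference(weights={}, n_compounds=0)
    weights = {
        site: sum(f.get(site, 0.0) for f in freqs) / len(freqs) for site in sorted(sites)
    }
    return SitePreference(weights=weights, n_compounds=len(freqs))


def _protein_polar_atoms(structure: Structure):
    """Heavy N/O atoms, with any hydrogen within 1.25 Å recorded as attached."""
    h_xyz = [a.xyz for a in structure.atoms if a.is_hydrogen]
    h_arr = np.asarray(h_xyz).reshape(-1, 3)
    donors = []  # (atom, [h coords])
    acceptors = []
    for a in structure.atoms:
        if a.element.upper() not in ("N", "O"):
            continue
        acceptors.append(a)
        if h_arr.shape[0]:
            d = np.linalg.norm(h_arr - a.xyz, axis=1)
            attached = [h_arr[i] for i in np.nonzero(d < 1.25)[0]]
            if attached:
                donors.append((a, attached))
    return donors, acceptors


def _hbond_angle(d_xyz, h_xyz, a_xyz) -> float:
    v1 = np.asarray(d_xyz, float) - np.asarray(h_xyz, float)
    v2 = np.asarray(a_xyz, float) - np.asarray(h_xyz, float)
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(
    pose: LigandPose,
    structure: Structure,
    d_max: float = 3.5,
    angle_min: float = 150.0,
    angle_max: float = 180.0,
) -> list[tuple[str, str, float, float]]:
    """Hydrogen bonds between pose and protein, both directions.

    A bond requires donor–acceptor distance < ``d_max`` (strict) and
    D–H···A angle within [``angle_min``, ``angle_max``] (inclusive).
    Returns (donor label, acceptor label, distance Å, angle °) tuples; atom
    labels are "ligand:<index>" or "protein:<chain>/<resid>/<name>".
    """
    prot_donors, prot_acceptors = _protein_polar_atoms(structure)
    out = []

    def atom_label(a) -> str:
        return f"protein:{a.chain}/{a.resid}/{a.name}"

    # ligand donor -> protein acceptor
    for di, h_xyz in pose.donors:
        d_xyz = pose.coords[di]
        for a in prot_acceptors:
            dist = float(np.linalg.norm(d_xyz - a.xyz))
            if dist >= d_max:
                continue
            ang = _hbond_angle(d_xyz, h_xyz, a.xyz)
            if angle_min <= ang <= angle_max:
                out.append((f"ligand:{di}", atom_label(a), dist, ang))
    # protein donor -> ligand acceptor
    for a, h_list in prot_donors:
        for ai in pose.acceptors:
            acc_xyz = pose.coords[ai]
            dist = float(np.linalg.norm(a.xyz - acc_xyz))
            if dist >= d_max:
                continue
            for h_xyz in h_list:
                ang = _hbond_angle(a.xyz, h_xyz, acc_xyz)
                if angle_min <= ang <= angle_max:
                    out.append((atom_label(a), f"ligand:{ai}", dist, ang))
                    break
    return out


def detect_vdw_contacts(
    pose: LigandPose,
    structure: Structure,
    cc_cutoff: float = 5.0,
) -> list[tuple[str, str, float]]:
    """All ligand-carbon / protein-carbon pairs closer than ``cc_cutoff`` Å."""
    lig_c = [i for i, e in enumerate(pose.elements) if e.upper() == "C"]
    prot_c = [a for a in structure.atoms if a.element.upper() == "C"]
    out = []
    for i in lig_c:
        for a in prot_c:
            d = float(np.linalg.norm(pose.coords[i] - a.xyz))
            if d < cc_cutoff:
                out.append((f"ligand:{i}", f"protein:{a.chain}/{a.resid}/{a.name}", d))
    return out


def rank_and_filter_binders(
    poses: Mapping[str, Sequence[LigandPose]],
    assignments: Mapping[str, Sequence[str]],
    descriptors: Mapping[str, CompoundDescriptors],
    consistency_threshold: float = 0.5,
    lipinski_mode: str = "classic",
    exclude_sites: Iterable[str] = (),
) -> pd.DataFrame:
    """Consistency-filtered, Lipinski-filtered, Ki-ranked hit table.

    A compound survives if (a) its modal site frequency reaches
    ``consistency_threshold``, (b) its modal site is not in
    ``exclude_sites`` (used to drop catalytic-site binders when the bound
    nucleotide marks that site), and (c) its descriptors pass the Lipinski
    filter.  Survivors are ranked ascending by best (lowest) predicted Ki;
    ties break by compound id.
    """
    exclude = set(exclude_sites)
    rows = []
    for cid in sorted(poses):
        pose_list = poses[cid]
        labels = list(assignments.get(cid, ()))
        if not pose_list or not labels:
            warnings.warn(f"compound {cid}: no poses/assignments; dropped")
            continue
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        modal_site = min(counts, key=lambda s: (-counts[s], s))
        freq = counts[modal_site] / len(labels)
        if freq < consistency_threshold:
            continue
        if modal_site in exclude or modal_site == UNASSIGNED:
            continue
        kis = [p.predicted_ki for p in pose_list if p.predicted_ki is not None]
        if not kis:
            warnings.warn(f"compound {cid}: no predicted Ki; dropped")
            continue
        desc = descriptors.get(cid)
        if desc is None:
            warnings.warn(f"compound {cid}: no descriptors; dropped")
            continue
        ok, violated = lipinski_filter(desc, mode=lipinski_mode)
        if not ok:
            continue
        rows.append(
            {
                "compound_id": cid,
                "site": modal_site,
                "site_frequency": freq,
                "best_ki": float(min(kis)),
                "lipinski_pass": True,
                "lipinski_violations": ";".join(violated),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "compound_id",
            "site",
            "site_frequency",
            "best_ki",
            "lipinski_pass",
            "lipinski_violations",
        ],
    )
    if len(df):
        df = df.sort_values(["best_ki", "compound_id"], kind="stable").reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
    else:
        df["rank"] = pd.Series(dtype=int)
    return df
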
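"""End-to-end pipeline driver: ensemble → representatives → pocket mapping →
volumetry → dock analysis → consensus triage.

A run is configured by a single YAML file (see :class:`PipelineConfig`);
every stage writes its interchange artifacts into the run directory and the
run manifest records the config hash, so reruns with identical config and
seed are reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .consensus_screen import (
    ScoreTable,
    consensus_union,
    descriptors_from_row,
    ensemble_overlap,
    load_reference_hit_descriptors,
    topk_per_function,
)
from .dock_analysis import (
    LigandPose,
    assign_pose_site,
    rank_and_filter_binders,
    site_preference,
)
from .ensemble_analysis import (
    ConformerEnsemble,
    cluster_conformers,
    find_invariant_core,
    fit_pca,
    select_representatives,
)
from .errors import ValidationError
from .pocket_mapping import (
    ProbePose,
    define_pockets,
    ensemble_occupancy,
    pocket_accessibility,
    pocket_volume,
    probe_contact_residues,
    write_pockets_json,
)
from .structure_io import read_pdb, write_pdb, write_pdb_with_profile

log = logging.getLogger("allosite")


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run.

    Defaults follow the field-standard values: 5.0 Å heavy-atom contact
    cutoff, 3.5 Å / 150–180° hydrogen bonds, 70-point energy envelopes,
    0.375 Å affinity-grid spacing, per-function top-20 consensus.
    """

    output_dir: str = "allosite_run"
    seed: int = 0
    # ensemble stage
    ensemble_manifest: str | None = None  # TSV: structure_id, path[, group]
    core_volume_threshold: float = 0.5
    k_clusters: int = 7
    # mapping stage
    contact_cutoff: float = 5.0
    occupancy_floor: float = 0.25
    pocket_link_distance: float = 8.0
    envelope_n_points: int = 70
    grid_spacing: float = 0.375
    # volumetry
    volume_spacing: float = 1.0
    inclusion_radius: float = 8.0
    # dock analysis
    hbond_distance: float = 3.5
    hbond_angle_min: float = 150.0
    hbond_angle_max: float = 180.0
    vdw_cc_cutoff: float = 5.0
    consistency_threshold: float = 0.5
    # consensus
    top_k: int = 20
    lipinski_mode: str = "classic"
    # synthetic mode (no external inputs required)
    synthetic: bool = True
    synthetic_n_residues: int = 40
    synthetic_cluster_sizes: tuple[int, ...] = (8, 7)
    synthetic_n_probe_poses: int = 20
    synthetic_hit_fraction: float = 0.8
    synthetic_n_compounds: int = 20
    synthetic_p3_preference: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "contact_cutoff",
            "hbond_distance",
            "vdw_cc_cutoff",
            "grid_spacing",
            "volume_spacing",
            "inclusion_radius",
            "pocket_link_distance",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0.0 < self.occupancy_floor <= 1.0):
            raise ValidationError("occupancy_floor must be in (0,1]")
        if self.k_clusters < 1 or self.top_k < 1 or self.envelope_n_points < 1:
            raise ValidationError("k_clusters, top_k, envelope_n_points must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "synthetic_cluster_sizes" in raw:
            raw["synthetic_cluster_sizes"] = tuple(raw["synthetic_cluster_sizes"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["synthetic_cluster_sizes"] = list(d["synthetic_cluster_sizes"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def digest(self) -> str:
        d = asdict(self)
        d["synthetic_cluster_sizes"] = list(d["synthetic_cluster_sizes"])
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_manifest(path) -> list:
    """Read an ensemble manifest TSV (structure_id, path[, group])."""
    df = pd.read_csv(path, sep="\t")
    if "structure_id" not in df.columns or "path" not in df.columns:
        raise ValidationError("manifest needs structure_id and path columns")
    base = Path(path).parent
    structures = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        structures.append(read_pdb(p, structure_id=str(row["structure_id"])))
    return structures


def poses_to_json(poses: dict, path) -> None:
    payload = {
        conf: [
            {
                "probe_id": p.probe_id,
                "elements": list(p.elements),
                "coords": np.asarray(p.coords).tolist(),
            }
            for p in plist
        ]
        for conf, plist in poses.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def poses_from_json(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        conf: [
            ProbePose(
                probe_id=d["probe_id"],
                elements=d["elements"],
                coords=np.asarray(d["coords"]),
                source_conformer=conf,
            )
            for d in plist
        ]
        for conf, plist in payload.items()
    }


def ligand_poses_to_json(poses: dict, path) -> None:
    payload = {
        cid: [
            {
                "pose_index": p.pose_index,
                "elements": list(p.elements),
                "coords": np.asarray(p.coords).tolist(),
                "donors": [[i, np.asarray(h).tolist()] for i, h in p.donors],
                "acceptors": list(p.acceptors),
                "predicted_ki": p.predicted_ki,
                "energy": p.energy,
            }
            for p in plist
        ]
        for cid, plist in poses.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def ligand_poses_from_json(path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        cid: [
            LigandPose(
                compound_id=cid,
                pose_index=d["pose_index"],
                elements=d["elements"],
                coords=np.asarray(d["coords"]),
                donors=[(i, np.asarray(h)) for i, h in d.get("donors", [])],
                acceptors=d.get("acceptors", []),
                predicted_ki=d.get("predicted_ki"),
                energy=d.get("energy"),
            )
            for d in plist
        ]
        for cid, plist in payload.items()
    }


def _stage(name: str):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage on synthetic or manifest inputs; returns the run dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)
    artifacts: list[str] = []

    def save(name: str) -> Path:
        artifacts.append(name)
        return out / name

    # ----- stage 1: ensemble -------------------------------------------------
    _stage("ensemble")
    truth = None
    if config.synthetic:
        spec = synthetic.clustered_ensemble_spec(
            n_residues=config.synthetic_n_residues,
            cluster_sizes=config.synthetic_cluster_sizes,
            separation=6.0,
            within_spread=0.4,
            noise_sd=0.1,
            seed=rng_seed,
        )
        ensemble, truth = synthetic.make_toy_ensemble(spec)
        for s in ensemble.structures:
            write_pdb(s, save(f"{s.id}.pdb"))
    else:
        if not config.ensemble_manifest:
            raise ValidationError("ensemble_manifest required when synthetic=false")
        structures = load_manifest(config.ensemble_manifest)
        ensemble = ConformerEnsemble.from_structures(structures)

    core = find_invariant_core(ensemble, volume_threshold=config.core_volume_threshold)
    model = fit_pca(ensemble)
    k = min(config.k_clusters, ensemble.n_conformers)
    clusters = cluster_conformers(model.projections[:, :3], k=k)
    reps = select_representatives(ensemble, clusters)
    log.info(
        "ensemble: %d conformers, core %d/%d positions, %d clusters",
        ensemble.n_conformers,
        len(core),
        ensemble.n_equiv,
        clusters.k,
    )

    proj = pd.DataFrame(
        model.projections[:, : min(3, model.n_components)],
        columns=[f"PC{i+1}" for i in range(min(3, model.n_components))],
        index=pd.Index(ensemble.ids, name="structure_id"),
    )
    proj.to_csv(save("pca_projections.tsv"), sep="\t")
    pd.DataFrame(
        {"eigenvalue_A2": model.eigenvalues[: model.n_components]}
    ).to_csv(save("pca_eigenvalues.tsv"), sep="\t", index_label="component")
    cl = pd.DataFrame(
        {
            "structure_id": ensemble.ids,
            "cluster": clusters.labels,
            "is_representative": [
                reps[clusters.labels[i]] == ensemble.ids[i]
                for i in range(ensemble.n_conformers)
            ],
        }
    )
    cl.to_csv(save("clusters.tsv"), sep="\t", index=False)
    rep_ids = sorted(set(reps.values()))
    rep_structures = [s for s in ensemble.structures if s.id in rep_ids]

    # ----- stage 2: probe mapping -------------------------------------------
    _stage("map")
    if config.synthetic:
        n_res = config.synthetic_n_residues
        planted = [tuple(range(2, 6)), tuple(range(n_res - 6, n_res - 2))]
        probe_poses = synthetic.make_probe_poses(
            ensemble,
            planted_pockets=planted,
            n_poses=config.synthetic_n_probe_poses,
            hit_fraction=config.synthetic_hit_fraction,
            seed=rng_seed + 1,
        )
    else:
        pose_file = out / "probe_poses.json"
        if not pose_file.exists():
            raise ValidationError(
                "non-synthetic runs expect probe_poses.json in the output dir"
            )
        probe_poses = poses_from_json(pose_file)

    by_id = {s.id: s for s in ensemble.structures}
    contacts = {
        conf: [
            probe_contact_residues(by_id[conf], p, cutoff=config.contact_cutoff)
            for p in plist
        ]
        for conf, plist in probe_poses.items()
        if conf in by_id
    }
    profile = ensemble_occupancy(contacts)
    occ_rows = profile.to_rows()
    pd.DataFrame(
        occ_rows, columns=["chain", "resid", "icode", "raw_count", "occupancy"]
    ).to_csv(save("occupancy.tsv"), sep="\t", index=False)
    ref = ensemble.structures[0]
    write_pdb_with_profile(ref, profile.values, save("occupancy_painted.pdb"))

    pockets = define_pockets(
        profile,
        ref,
        occupancy_floor=config.occupancy_floor,
        link_distance=config.pocket_link_distance,
    )
    pockets = pocket_accessibility(pockets, contacts)
    log.info("map: %d pockets from %d hot residues", len(pockets), len(profile.values))

    # ----- stage 3: volumetry ------------------------------------------------
    _stage("volume")
    measured = []
    from .pocket_mapping import Pocket

    for p in pockets:
        vols, mean, sd = pocket_volume(
            rep_structures,
            p,
            spacing=config.volume_spacing,
            inclusion_radius=config.inclusion_radius,
        )
        measured.append(
            Pocket(
                pocket_id=p.pocket_id,
                residues=p.residues,
                accessible_in=p.accessible_in,
                volume_mean=mean,
                volume_sd=sd,
                is_active_site=p.is_active_site,
            )
        )
    pockets = measured
    write_pockets_json(pockets, save("pockets.json"))

    # ----- stage 4: dock analysis -------------------------------------------
    _stage("dock")
    if not pockets:
        raise ValidationError("no pockets found; cannot run dock analysis")
    if config.synthetic:
        n_p = len(pockets)
        pref = np.zeros(n_p + 1)
        pref[0] = config.synthetic_p3_preference
        rest = 1.0 - config.synthetic_p3_preference
        pref[1:] = rest / n_p if n_p else rest
        pref[-1] += 1.0 - pref.sum()
        dock_poses, _truth_sites = synthetic.make_dock_poses(
            ref,
            pockets,
            preference=pref,
            n_compounds=config.synthetic_n_compounds,
            seed=rng_seed + 2,
        )
    else:
        lig_file = out / "ligand_poses.json"
        if not lig_file.exists():
            raise ValidationError(
                "non-synthetic runs expect ligand_poses.json in the output dir"
            )
        dock_poses = ligand_poses_from_json(lig_file)

    assignments = {
        cid: [
            assign_pose_site(p, ref, pockets, cutoff=config.contact_cutoff)
            for p in plist
        ]
        for cid, plist in dock_poses.items()
    }
    pref_result = site_preference(assignments)
    with open(save("site_preference.json"), "w") as fh:
        json.dump(
            {"weights": pref_result.weights, "n_compounds": pref_result.n_compounds},
            fh,
            indent=1,
            sort_keys=True,
        )
    log.info("dock: site preference %s", pref_result.weights)

    ref_desc = load_reference_hit_descriptors()
    desc_pool = [descriptors_from_row(r) for _, r in ref_desc.iterrows()]
    descriptors = {}
    for i, cid in enumerate(sorted(dock_poses)):
        d = desc_pool[i % len(desc_pool)]
        descriptors[cid] = type(d)(
            compound_id=cid, nOHNH=d.nOHNH, nON=d.nON, mw=d.mw, logp=d.logp
        )
    hits = rank_and_filter_binders(
        dock_poses,
        assignments,
        descriptors,
        consistency_threshold=config.consistency_threshold,
        lipinski_mode=config.lipinski_mode,
    )
    hits.to_csv(save("dock_hits.csv"), index=False)

    # ----- stage 5: consensus ------------------------------------------------
    _stage("consensus")
    cryst_table = synthetic.make_score_table(
        n_compounds=max(50, config.synthetic_n_compounds),
        n_functions=8,
        rank_agreement=0.9,
        seed=rng_seed + 3,
        ensemble_tag="crystallographic",
    )
    md_table = synthetic.make_score_table(
        n_compounds=max(50, config.synthetic_n_compounds),
        n_functions=8,
        rank_agreement=0.9,
        seed=rng_seed + 4,
        ensemble_tag="md",
    )
    cryst_table.to_csv(save("scores_cryst.csv"), save("scores_cryst_orientation.json"))
    md_table.to_csv(save("scores_md.csv"), save("scores_md_orientation.json"))
    cryst_hits = consensus_union(topk_per_function(cryst_table, k=config.top_k))
    md_hits = consensus_union(topk_per_function(md_table, k=config.top_k))
    site_map_c = {c: "p1" for c in cryst_hits.members}
    site_map_m = {c: "p1" for c in md_hits.members}
    shared, md_only, cryst_only = ensemble_overlap(
        cryst_hits, md_hits, site_map_c, site_map_m
    )
    with open(save("consensus.json"), "w") as fh:
        json.dump(
            {
                "crystallographic_hits": sorted(cryst_hits.members),
                "md_hits": sorted(md_hits.members),
                "shared": sorted(shared),
                "md_only": sorted(md_only),
                "cryst_only": sorted(cryst_only),
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    log.info(
        "consensus: %d cryst, %d md, %d shared, %d md-only",
        len(cryst_hits.members),
        len(md_hits.members),
        len(shared),
        len(md_only),
    )

    # ----- manifest ----------------------------------------------------------
    config.to_yaml(save("config.yaml"))
    manifest = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "artifacts": sorted(artifacts),
        "n_conformers": ensemble.n_conformers,
        "n_pockets": len(pockets),
        "n_dock_hits": int(len(hits)),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return out
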
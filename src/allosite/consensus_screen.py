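"""Virtual-screen triage: per-function top-k consensus, ensemble hit overlap,
Tanimoto similarity, and Lipinski rule-of-five descriptors/filtering.

Scores from different scoring functions are never compared on their raw
scales — each function's orientation (lower-better vs higher-better) must be
declared and only ranks are merged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "ScoreTable",
    "CompoundDescriptors",
    "HitSet",
    "Molecule",
    "topk_per_function",
    "consensus_union",
    "ensemble_overlap",
    "tanimoto",
    "compute_lipinski_descriptors",
    "lipinski_filter",
    "load_reference_hit_descriptors",
]


@dataclass
class ScoreTable:
    """Compound × scoring-function matrix with declared orientations.

    ``orientation[fn]`` is "lower" (better scores are smaller, e.g. energies)
    or "higher" (better scores are larger).
    """

    scores: pd.DataFrame  # index: compound_id, columns: function names
    orientation: dict[str, str]
    ensemble_tag: str = ""

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            raise ValidationError("duplicate compound ids in score table")
        for fn in self.scores.columns:
            o = self.orientation.get(fn)
            if o not in ("lower", "higher"):
                raise ValidationError(f"function {fn!r}: orientation must be declared")

    @property
    def compounds(self) -> list[str]:
        return list(self.scores.index)

    @property
    def functions(self) -> list[str]:
        return list(self.scores.columns)

    @classmethod
    def from_csv(cls, csv_path, orientation_json, ensemble_tag: str = "") -> "ScoreTable":
        df = pd.read_csv(csv_path, index_col=0)
        df.index = df.index.astype(str)
        with open(orientation_json) as fh:
            orientation = json.load(fh)
        return cls(scores=df, orientation=orientation, ensemble_tag=ensemble_tag)

    def to_csv(self, csv_path, orientation_json) -> None:
        self.scores.to_csv(csv_path, index_label="compound_id")
        with open(orientation_json, "w") as fh:
            json.dump(self.orientation, fh, indent=1, sort_keys=True)


def topk_per_function(table: ScoreTable, k: int = 20) -> dict[str, list[str]]:
    """Per scoring function, the k best-ranked compound ids.

    Sorting respects each function's declared orientation; ties are broken
    stably by compound id.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    n = len(table.compounds)
    if k > n:
        warnings.warn(f"k={k} exceeds {n} compounds; returning full lists")
        k = n
    out: dict[str, list[str]] = {}
    for fn in table.functions:
        col = table.scores[fn]
        sign = 1.0 if table.orientation[fn] == "lower" else -1.0
        order = sorted(col.index, key=lambda cid: (sign * col[cid], cid))
        out[fn] = order[:k]
    return out


@dataclass
class HitSet:
    """A set of hit compounds with provenance (which lists produced each)."""

    members: frozenset[str]
    provenance: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        self.provenance = {m: frozenset(v) for m, v in self.provenance.items()}
        for m in self.members:
            if not self.provenance.get(m):
                raise ValidationError(f"hit {m} has empty provenance")

    def to_dict(self) -> dict:
        return {m: sorted(self.provenance[m]) for m in sorted(self.members)}


def consensus_union(per_function_lists: Mapping[str, Sequence[str]]) -> HitSet:
    """Union of per-function top-k lists, recording provenance per compound."""
    if not per_function_lists:
        raise ValidationError("need at least one ranked list")
    prov: dict[str, set[str]] = {}
    for fn, lst in per_function_lists.items():
        for cid in lst:
            prov.setdefault(str(cid), set()).add(str(fn))
    return HitSet(
        members=frozenset(prov), provenance={m: frozenset(v) for m, v in prov.items()}
    )


def ensemble_overlap(
    cryst: HitSet,
    md: HitSet,
    cryst_sites: Mapping[str, str],
    md_sites: Mapping[str, str],
) -> tuple[frozenset[str], frozenset[str], frozenset[str]]:
    """(shared, md_only, cryst_only) hit partition across the two ensembles.

    ``shared`` requires membership in both hit sets *and* matching assigned
    site; ``md_only`` are MD members absent from the crystallographic set
    (and vice versa).
    """
    both = cryst.members & md.members
    shared = frozenset(
        c for c in both if cryst_sites.get(c) is not None and cryst_sites.get(c) == md_sites.get(c)
    )
    md_only = frozenset(md.members - cryst.members)
    cryst_only = frozenset(cryst.members - md.members)
    return shared, md_only, cryst_only


def tanimoto(fp_a: Iterable, fp_b: Iterable) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| on fingerprint bit sets (∅,∅ → 0)."""
    a, b = set(fp_a), set(fp_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


# ---------------------------------------------------------------------------
# Lipinski descriptors and filter
# ---------------------------------------------------------------------------


@dataclass
class Molecule:
    """Minimal small-molecule graph: explicit atoms and bonds.

    ``bonds`` are index pairs into ``elements``; hydrogens must be explicit
    for donor counting.
    """

    compound_id: str
    elements: list[str]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    logp: float | None = None


@dataclass
class CompoundDescriptors:
    """Lipinski descriptors: donor count (nOHNH), acceptor count (nON),
    molecular weight (g/mol) and logP."""

    compound_id: str
    nOHNH: int
    nON: int
    mw: float
    logp: float

    def __post_init__(self) -> None:
        if self.nOHNH < 0 or self.nON < 0:
            raise ValidationError("descriptor counts must be >= 0")
        if self.mw <= 0:
            raise ValidationError("molecular weight must be positive")


def compute_lipinski_descriptors(mol: Molecule) -> CompoundDescriptors:
    """Count H-bond donors/acceptors and sum the molecular weight.

    nON counts N and O atoms; nOHNH counts hydrogens bonded to N or O;
    MW sums standard atomic weights.  logP is passed through from the input
    (no in-house logP model) and defaults to 0.0 when absent.
    """
    elements = [e.capitalize() for e in mol.elements]
    mw = 0.0
    for e in elements:
        el = gemmi.Element(e)
        if el.name in ("X", "") or el.atomic_number == 0:
            raise ValidationError(f"unknown element {e!r} in {mol.compound_id}")
        mw += el.weight
    n_on = sum(1 for e in elements if e in ("N", "O"))
    polar = {i for i, e in enumerate(elements) if e in ("N", "O")}
    n_ohnh = 0
    for i, j in mol.bonds:
        if elements[i] == "H" and j in polar:
            n_ohnh += 1
        elif elements[j] == "H" and i in polar:
            n_ohnh += 1
    return CompoundDescriptors(
        compound_id=mol.compound_id,
        nOHNH=n_ohnh,
        nON=n_on,
        mw=mw,
        logp=mol.logp if mol.logp is not None else 0.0,
    )


_LIPINSKI_RULES = (
    ("donors", lambda d: d.nOHNH <= 5),
    ("acceptors", lambda d: d.nON <= 10),
    ("mw", lambda d: d.mw <= 500.0),
    ("logp", lambda d: d.logp <= 5.0),
)


def lipinski_filter(d: CompoundDescriptors, mode: str = "classic") -> tuple[bool, list[str]]:
    """Rule-of-five filter: donors ≤5, acceptors ≤10, MW ≤500, logP ≤5.

    ``strict`` passes only with zero violations; ``classic`` tolerates one
    (the conventional "fails if it breaks two or more rules" reading).
    Bounds are inclusive.  Returns (pass, violated rule names).
    """
    violated = [name for name, ok in _LIPINSKI_RULES if not ok(d)]
    if mode == "strict":
        return len(violated) == 0, violated
    if mode == "classic":
        return len(violated) <= 1, violated
    raise ValidationError(f"unknown Lipinski mode {mode!r}")


def load_reference_hit_descriptors() -> pd.DataFrame:
    """Published descriptor table for the 19 Ras ensemble-screening hits.

    Columns: compound_id, dataset, pocket, nOHNH, nON, logp, mw.
    """
    with resources.files("allosite.data").joinpath("ras_screen_hits.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"compound_id": str})
    return df


def descriptors_from_row(row) -> CompoundDescriptors:
    return CompoundDescriptors(
        compound_id=str(row["compound_id"]),
        nOHNH=int(row["nOHNH"]),
        nON=int(row["nON"]),
        mw=float(row["mw"]),
        logp=float(row["logp"]),
    )
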
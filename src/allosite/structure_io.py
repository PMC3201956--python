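"""Protein structure I/O and atom selection.

Structures are read from PDB files (via gemmi) into a flat list of
:class:`Atom` records.  Residue identity is the triple ``(chain, resid,
icode)``; most public functions also accept the two-tuple ``(chain, resid)``
which is normalised with an empty insertion code.  Coordinates are Angstroms
throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import gemmi
import numpy as np

from .errors import MalformedStructureError, ValidationError

#: residue names treated as bound nucleotide by default
DEFAULT_NUCLEOTIDE_RESNAMES = frozenset({"GTP", "GDP", "GNP", "GSP", "GCP"})

_WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})


class ResidueId(NamedTuple):
    """Identity of a residue: chain id, author residue number, insertion code."""

    chain: str
    resid: int
    icode: str = ""


def as_residue_id(key) -> ResidueId:
    """Normalise ``(chain, resid)`` / ``(chain, resid, icode)`` tuples."""
    if isinstance(key, ResidueId):
        return key
    if len(key) == 2:
        return ResidueId(str(key[0]), int(key[1]), "")
    if len(key) == 3:
        return ResidueId(str(key[0]), int(key[1]), str(key[2]))
    raise ValidationError(f"cannot interpret residue key {key!r}")


@dataclass(frozen=True)
class Atom:
    """One atom record.

    ``bfactor`` doubles as the per-residue paint channel when profiles are
    written back out to PDB.
    """

    serial: int
    name: str
    element: str
    resname: str
    resid: int
    chain: str
    coord: tuple[float, float, float]
    icode: str = ""
    is_hetero: bool = False
    bfactor: float = 0.0
    occupancy: float = 1.0

    @property
    def residue_id(self) -> ResidueId:
        return ResidueId(self.chain, self.resid, self.icode)

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coord, dtype=float)


@dataclass
class Structure:
    """A single protein conformer: ordered atoms plus het groups."""

    id: str
    atoms: list[Atom]
    nucleotide_resnames: frozenset[str] = field(default=DEFAULT_NUCLEOTIDE_RESNAMES)

    def __post_init__(self) -> None:
        coords = self.coords
        if coords.size and not np.all(np.isfinite(coords)):
            raise ValidationError(f"structure {self.id}: non-finite coordinates")

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array."""
        return np.array([a.coord for a in self.atoms], dtype=float).reshape(-1, 3)

    def residues(self) -> dict[ResidueId, list[int]]:
        """Ordered mapping residue id -> atom indices."""
        out: dict[ResidueId, list[int]] = {}
        for i, atom in enumerate(self.atoms):
            out.setdefault(atom.residue_id, []).append(i)
        return out

    def polymer_residues(self) -> dict[ResidueId, list[int]]:
        """Residues that are not het groups (at least one non-HETATM atom)."""
        out: dict[ResidueId, list[int]] = {}
        for i, atom in enumerate(self.atoms):
            if not atom.is_hetero:
                out.setdefault(atom.residue_id, []).append(i)
        return out

    def calpha_index(self) -> dict[ResidueId, int]:
        """Residue id -> atom index of its C-alpha."""
        out: dict[ResidueId, int] = {}
        for i, atom in enumerate(self.atoms):
            if atom.name == "CA" and not atom.is_hetero and atom.element.upper() != "CA":
                out.setdefault(atom.residue_id, i)
        return out

    def heavy_indices(self, include_hetero: bool = True) -> np.ndarray:
        idx = [
            i
            for i, a in enumerate(self.atoms)
            if not a.is_hydrogen and (include_hetero or not a.is_hetero)
        ]
        return np.asarray(idx, dtype=int)

    def nucleotide_atom_indices(self) -> np.ndarray:
        idx = [i for i, a in enumerate(self.atoms) if a.resname in self.nucleotide_resnames]
        return np.asarray(idx, dtype=int)

    def select(self, spec: str) -> np.ndarray:
        return select(self, spec)


def _resolve_altlocs(records: list[tuple[str, float, Atom]]) -> Atom:
    """Keep the highest-occupancy alternate location; ties -> first encountered."""
    best = None
    best_occ = -np.inf
    for _altloc, occ, atom in records:
        if occ > best_occ + 1e-9:
            best, best_occ = atom, occ
    assert best is not None
    return best


def read_pdb(
    path,
    model: int | None = None,
    keep_waters: bool = False,
    nucleotide_resnames: Iterable[str] = DEFAULT_NUCLEOTIDE_RESNAMES,
    structure_id: str | None = None,
) -> Structure:
    """Read one conformer from a PDB file.

    Parameters
    ----------
    path : path-like
        PDB file (v3.3 fixed columns).
    model : int, optional
        MODEL record number to extract from a multi-model file; default is
        the first model.
    keep_waters : bool
        Retain water residues (dropped by default).
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, OSError, ValueError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise MalformedStructureError(f"{path}: no models")
    if model is None:
        gmodel = st[0]
    else:
        matches = [m for m in st if m.num == model]
        if not matches:
            raise ValidationError(f"{path}: no MODEL {model} (available: {[m.num for m in st]})")
        gmodel = matches[0]

    atoms: list[Atom] = []
    serial = 0
    for chain in gmodel:
        for res in chain:
            if not keep_waters and res.name in _WATER_RESNAMES:
                continue
            is_het = res.het_flag == "H"
            icode = res.seqid.icode.strip()
            # group alternate locations per atom name
            by_name: dict[str, list[tuple[str, float, Atom]]] = {}
            order: list[str] = []
            for at in res:
                serial += 1
                atom = Atom(
                    serial=serial,
                    name=at.name,
                    element=at.element.name,
                    resname=res.name,
                    resid=res.seqid.num,
                    chain=chain.name,
                    coord=(at.pos.x, at.pos.y, at.pos.z),
                    icode=icode,
                    is_hetero=is_het,
                    bfactor=at.b_iso,
                    occupancy=at.occ,
                )
                if at.name not in by_name:
                    order.append(at.name)
                by_name.setdefault(at.name, []).append((at.altloc, at.occ, atom))
            for name in order:
                atoms.append(_resolve_altlocs(by_name[name]))

    sid = structure_id if structure_id is not None else st.name or str(path)
    structure = Structure(
        id=sid, atoms=atoms, nucleotide_resnames=frozenset(nucleotide_resnames)
    )
    if not structure.calpha_index():
        raise MalformedStructureError(f"{path}: no C-alpha atoms found")
    return structure


def _format_pdb_line(atom: Atom, serial: int, bfactor: float) -> str:
    record = "HETATM" if atom.is_hetero else "ATOM  "
    name = atom.name
    # standard alignment: element symbols of one letter start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = " " + name
    x, y, z = atom.coord
    return (
        f"{record}{serial:>5d} {name:<4s}{'':1s}{atom.resname:>3s} {atom.chain[:1]:1s}"
        f"{atom.resid:>4d}{atom.icode[:1]:<1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{bfactor:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(structure: Structure, path) -> None:
    """Write a structure as fixed-column PDB, preserving stored B-factors."""
    lines = []
    for i, atom in enumerate(structure.atoms, start=1):
        lines.append(_format_pdb_line(atom, i, atom.bfactor))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_pdb_with_profile(
    structure: Structure,
    per_residue_values: Mapping,
    path,
) -> None:
    """Write a PDB whose B column carries a per-residue profile.

    Values must lie in [0, 1]; they are scaled to [0, 99.99] with fixed
    2-decimal formatting so molecular viewers can colour by B-factor.
    Residues absent from the map get 0.00.
    """
    values = {as_residue_id(k): float(v) for k, v in per_residue_values.items()}
    for key, v in values.items():
        if not np.isfinite(v) or v < 0.0 or v > 1.0:
            raise ValidationError(f"profile value for {key} out of [0,1]: {v}")
    lines = []
    for i, atom in enumerate(structure.atoms, start=1):
        b = values.get(atom.residue_id, 0.0) * 99.99
        lines.append(_format_pdb_line(atom, i, b))
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# selection grammar:  expr := term ('or' term)* ; term := factor ('and' factor)*
# factor := 'not' factor | '(' expr ')' | primitive
# primitives: calpha | heavy | carbon | hetero | all | chain X | resid RANGES
# ---------------------------------------------------------------------------


def _tokenize(spec: str) -> list[str]:
    out = []
    for tok in spec.replace("(", " ( ").replace(")", " ) ").split():
        out.append(tok)
    return out


class _SelParser:
    def __init__(self, structure: Structure, tokens: list[str]):
        self.s = structure
        self.toks = tokens
        self.pos = 0
        self.n = len(structure.atoms)

    def peek(self):
        return self.toks[self.pos] if self.pos < len(self.toks) else None

    def take(self):
        tok = self.peek()
        if tok is None:
            raise ValidationError("unexpected end of selection expression")
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        mask = self.expr()
        if self.peek() is not None:
            raise ValidationError(f"trailing tokens in selection: {self.toks[self.pos:]}")
        return mask

    def expr(self) -> np.ndarray:
        mask = self.term()
        while self.peek() == "or":
            self.take()
            mask = mask | self.term()
        return mask

    def term(self) -> np.ndarray:
        mask = self.factor()
        while self.peek() == "and":
            self.take()
            mask = mask & self.factor()
        return mask

    def factor(self) -> np.ndarray:
        tok = self.peek()
        if tok == "not":
            self.take()
            return ~self.factor()
        if tok == "(":
            self.take()
            mask = self.expr()
            if self.take() != ")":
                raise ValidationError("unbalanced parentheses in selection")
            return mask
        return self.primitive()

    def primitive(self) -> np.ndarray:
        tok = self.take().lower()
        atoms = self.s.atoms
        if tok == "calpha":
            return np.array(
                [a.name == "CA" and not a.is_hetero for a in atoms], dtype=bool
            )
        if tok == "heavy":
            return np.array([not a.is_hydrogen for a in atoms], dtype=bool)
        if tok == "carbon":
            return np.array([a.element.upper() == "C" for a in atoms], dtype=bool)
        if tok == "hetero":
            return np.array([a.is_hetero for a in atoms], dtype=bool)
        if tok == "all":
            return np.ones(self.n, dtype=bool)
        if tok == "chain":
            chain = self.take()
            return np.array([a.chain == chain for a in atoms], dtype=bool)
        if tok == "resid":
            arg = self.take()
            wanted = _expand_resid_ranges(arg)
            return np.array([a.resid in wanted for a in atoms], dtype=bool)
        raise ValidationError(f"unknown selection token {tok!r}")


def _expand_resid_ranges(arg: str) -> set[int]:
    wanted: set[int] = set()
    for part in arg.split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part[1:]:  # allow negative resids in first position
            lo, hi = part.rsplit("-", 1)
            try:
                lo_i, hi_i = int(lo), int(hi)
            except ValueError as exc:
                raise ValidationError(f"bad resid range {part!r}") from exc
            if hi_i < lo_i:
                raise ValidationError(f"empty resid range {part!r}")
            wanted.update(range(lo_i, hi_i + 1))
        else:
            try:
                wanted.add(int(part))
            except ValueError as exc:
                raise ValidationError(f"bad resid {part!r}") from exc
    return wanted


def select(structure: Structure, spec: str) -> np.ndarray:
    """Evaluate a selection expression; returns sorted atom indices.

    Grammar: ``calpha | heavy | carbon | hetero | all | chain <id> |
    resid <n,n-m,...>`` combined with ``and``, ``or``, ``not`` and
    parentheses.  The empty selection is allowed.
    """
    tokens = _tokenize(spec)
    if not tokens:
        raise ValidationError("empty selection expression")
    mask = _SelParser(structure, tokens).parse()
    return np.nonzero(mask)[0]
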
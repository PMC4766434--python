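"""Crystal structures: PDB I/O, unit cells, space-group symmetry, mate generation.

The inactive conformation of a multi-domain kinase is often not present in the
asymmetric unit of a crystal: the physiological inter-domain packing is
recapitulated by a *symmetry mate* in a neighboring unit cell.  This module
provides the machinery to find such mates — parse a PDB file with its CRYST1
record, apply fractional-frame space-group operators plus lattice translations,
and enumerate the images of one domain that come close to another.

Heavy lifting (PDB records, cell orthogonalization, the space-group operator
table) is delegated to gemmi; the types here are the thin, explicit containers
the rest of the pipeline works with.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import GeometryError, ParseError

__all__ = [
    "Atom3D",
    "ResidueRecord",
    "UnitCell",
    "SymOp",
    "StructureModel",
    "DomainAnnotation",
    "SymmetryMate",
    "parse_structure",
    "convert_coordinates",
    "apply_symop",
    "generate_symmetry_mates",
    "select_domain",
    "write_pdb",
]

# Space groups whose operator tables are exercised by the test suite; any
# Hermann-Mauguin symbol known to gemmi is accepted.
SUPPORTED_SPACEGROUPS = ("P 1", "P 21", "P 21 21 21", "C 2", "P 21 21 2", "P 43 21 2")


@dataclass(frozen=True)
class Atom3D:
    serial: int
    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        if not self.element:
            raise ParseError(f"atom {self.name} (serial {self.serial}) has no element")
        if not all(np.isfinite(self.coords)):
            raise ParseError(f"atom {self.name} (serial {self.serial}) has non-finite coordinates")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)


@dataclass(frozen=True)
class ResidueRecord:
    chain_id: str
    resnum: int
    icode: str
    resname: str
    atoms: tuple[Atom3D, ...]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ParseError(f"residue {self.resname} {self.chain_id}{self.resnum} has no atoms")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.resnum, self.icode)

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.resname}{self.resnum}{self.icode.strip()}"

    def heavy_atoms(self) -> list[Atom3D]:
        return [a for a in self.atoms if a.is_heavy]


@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise GeometryError("unit cell edges must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0 < ang < 180:
                raise GeometryError("unit cell angles must lie in (0, 180) degrees")

    def to_gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class SymOp:
    """A crystallographic operator in the fractional frame: x' = rot @ x + trans."""

    rot: tuple[tuple[float, float, float], ...]
    trans: tuple[float, float, float]
    label: str

    @property
    def rot_matrix(self) -> np.ndarray:
        return np.asarray(self.rot, dtype=float)

    @property
    def trans_vector(self) -> np.ndarray:
        return np.asarray(self.trans, dtype=float)

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.rot_matrix, np.eye(3)) and np.allclose(self.trans_vector, 0.0)

    @classmethod
    def identity(cls) -> "SymOp":
        return cls(rot=((1.0, 0, 0), (0, 1.0, 0), (0, 0, 1.0)), trans=(0.0, 0.0, 0.0), label="x,y,z")

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymOp":
        """Build an operator from an ``x,y,z``-style triplet (e.g. ``-x,y+1/2,-z``)."""
        try:
            op = gemmi.Op(triplet)
        except Exception as exc:  # gemmi raises RuntimeError on bad triplets
            raise ParseError(f"invalid symmetry operator triplet {triplet!r}: {exc}") from exc
        return cls.from_gemmi(op)

    @classmethod
    def from_gemmi(cls, op: gemmi.Op) -> "SymOp":
        den = float(op.DEN)
        rot = tuple(tuple(v / den for v in row) for row in op.rot)
        trans = tuple(v / den for v in op.tran)
        return cls(rot=rot, trans=trans, label=op.triplet())


@dataclass
class StructureModel:
    chains: dict[str, list[ResidueRecord]]
    cell: UnitCell | None
    spacegroup: str | None
    symops: list[SymOp] = field(default_factory=lambda: [SymOp.identity()])

    def __post_init__(self) -> None:
        if not self.symops or not any(op.is_identity for op in self.symops):
            raise GeometryError("symmetry operator list must contain the identity")
        seen: set[tuple[str, int, str]] = set()
        for residues in self.chains.values():
            for res in residues:
                if res.key in seen:
                    raise ParseError(f"duplicate residue {res.label} in model")
                seen.add(res.key)

    @property
    def cell_defined(self) -> bool:
        return self.cell is not None

    def residues(self) -> list[ResidueRecord]:
        return [res for residues in self.chains.values() for res in residues]

    def atoms(self) -> list[Atom3D]:
        return [a for res in self.residues() for a in res.atoms]

    def get_residue(self, chain_id: str, resnum: int, icode: str = " ") -> ResidueRecord:
        for res in self.chains.get(chain_id, []):
            if res.resnum == resnum and res.icode == icode:
                return res
        raise GeometryError(f"residue {chain_id}:{resnum}{icode.strip()} not found in model")


@dataclass(frozen=True)
class DomainAnnotation:
    """A named contiguous residue span (author numbering, inclusive) on one chain."""

    name: str
    chain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise GeometryError(f"domain {self.name}: span {self.start}-{self.end} is empty")

    def contains(self, resnum: int) -> bool:
        return self.start <= resnum <= self.end

    def overlaps(self, start: int, end: int) -> bool:
        return not (end < self.start or start > self.end)


@dataclass(frozen=True)
class SymmetryMate:
    """A symmetry image of a domain, with the operator that produced it."""

    op: SymOp
    op_index: int
    shift: tuple[int, int, int]
    residues: tuple[ResidueRecord, ...]
    min_distance: float

    @property
    def label(self) -> str:
        return f"{self.op.label} + ({self.shift[0]},{self.shift[1]},{self.shift[2]})"


# --------------------------------------------------------------------------
# Parsing and writing
# --------------------------------------------------------------------------

def _validate_atom_records(pdb_text: str) -> None:
    """Reject malformed ATOM/HETATM records, naming the offending line."""
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise ParseError(f"line {lineno}: ATOM record too short ({len(line)} columns)")
        try:
            float(line[30:38])
            float(line[38:46])
            float(line[46:54])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: unreadable coordinates in ATOM record") from exc
        try:
            int(line[22:26])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: unreadable residue number in ATOM record") from exc


def _spacegroup_ops(symbol: str) -> list[SymOp]:
    try:
        sg = gemmi.SpaceGroup(symbol)
    except Exception as exc:
        raise ParseError(
            f"unknown space-group symbol {symbol!r}; supported symbols include "
            f"{', '.join(SUPPORTED_SPACEGROUPS)} and any standard Hermann-Mauguin name"
        ) from exc
    ops = [SymOp.from_gemmi(op) for op in sg.operations()]
    # Put the identity first for deterministic operator indexing.
    ops.sort(key=lambda op: (not op.is_identity, op.label))
    return ops


def parse_structure(pdb_text: str) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Author residue numbering is preserved.  When a CRYST1 record is present the
    unit cell and the full space-group operator table are attached; otherwise
    the cell is undefined and only the identity operator is available.  For
    alternate locations, the highest-occupancy conformer of each atom is kept.
    Water molecules are dropped.
    """
    _validate_atom_records(pdb_text)
    has_cryst1 = any(line.startswith("CRYST1") for line in pdb_text.splitlines())
    try:
        st = gemmi.read_pdb_string(pdb_text)
    except Exception as exc:
        raise ParseError(f"unreadable PDB text: {exc}") from exc

    if len(st) == 0:
        raise ParseError("PDB text contains no ATOM/HETATM records")

    cell: UnitCell | None = None
    spacegroup: str | None = None
    symops = [SymOp.identity()]
    if has_cryst1 and st.cell.a > 0:
        cell = UnitCell(st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma)
        spacegroup = st.spacegroup_hm or "P 1"
        symops = _spacegroup_ops(spacegroup)

    chains: dict[str, list[ResidueRecord]] = {}
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name == "HOH":
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            atoms = tuple(
                Atom3D(
                    serial=a.serial,
                    name=a.name,
                    element=a.element.name,
                    coords=(a.pos.x, a.pos.y, a.pos.z),
                    occupancy=a.occ,
                )
                for a in best.values()
            )
            if not atoms:
                continue
            chains.setdefault(chain.name, []).append(
                ResidueRecord(
                    chain_id=chain.name,
                    resnum=res.seqid.num,
                    icode=res.seqid.icode if res.seqid.icode.strip() else " ",
                    resname=res.name,
                    atoms=atoms,
                )
            )
    if not chains:
        raise ParseError("PDB text contains no polymer atoms")
    return StructureModel(chains=chains, cell=cell, spacegroup=spacegroup, symops=symops)


def write_pdb(
    residues: list[ResidueRecord],
    cell: UnitCell | None = None,
    spacegroup: str | None = None,
) -> str:
    """Serialize residues to PDB-format text (CRYST1 + ATOM + TER + END)."""
    lines: list[str] = []
    if cell is not None:
        sg = spacegroup or "P 1"
        lines.append(
            f"CRYST1{cell.a:9.3f}{cell.b:9.3f}{cell.c:9.3f}"
            f"{cell.alpha:7.2f}{cell.beta:7.2f}{cell.gamma:7.2f} {sg:<11s}"
        )
    serial = 0
    prev_chain: str | None = None
    for res in residues:
        if prev_chain is not None and res.chain_id != prev_chain:
            lines.append("TER")
        prev_chain = res.chain_id
        for atom in res.atoms:
            serial += 1
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            x, y, z = atom.coords
            lines.append(
                f"ATOM  {serial:5d} {name}{'':1s}{res.resname:>3s} {res.chain_id:1s}"
                f"{res.resnum:4d}{res.icode:1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{atom.occupancy:6.2f}{0.0:6.2f}          {atom.element:>2s}"
            )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# Coordinate frames and symmetry
# --------------------------------------------------------------------------

def convert_coordinates(v, cell: UnitCell | None, direction: str) -> np.ndarray:
    """Convert one 3-vector between orthogonal (Å) and fractional frames.

    ``direction`` is ``"orth_to_frac"`` or ``"frac_to_orth"``.
    """
    if cell is None:
        raise GeometryError("cannot convert coordinates: unit cell is undefined")
    g = cell.to_gemmi()
    x, y, z = (float(c) for c in v)
    if direction == "orth_to_frac":
        f = g.fractionalize(gemmi.Position(x, y, z))
        return np.array([f.x, f.y, f.z])
    if direction == "frac_to_orth":
        p = g.orthogonalize(gemmi.Fractional(x, y, z))
        return np.array([p.x, p.y, p.z])
    raise ValueError(f"direction must be 'orth_to_frac' or 'frac_to_orth', got {direction!r}")


def _frame_matrices(cell: UnitCell) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonalization matrix M (frac->orth) and its inverse."""
    g = cell.to_gemmi()
    m = np.array(g.orth.mat.tolist(), dtype=float)
    return m, np.linalg.inv(m)


def apply_symop(
    atoms: list[Atom3D],
    op: SymOp,
    cell: UnitCell | None,
    shift: tuple[int, int, int] = (0, 0, 0),
) -> list[Atom3D]:
    """Apply a fractional-frame operator (plus an integer lattice shift) to atoms.

    Symmetry operations are isometries: all pairwise interatomic distances are
    preserved.  The identity with zero shift is allowed on an undefined cell.
    """
    if op.is_identity and shift == (0, 0, 0):
        return list(atoms)
    if cell is None:
        raise GeometryError("cannot apply a non-identity symmetry operator: unit cell undefined")
    m, m_inv = _frame_matrices(cell)
    coords = np.array([a.coords for a in atoms], dtype=float)
    frac = coords @ m_inv.T
    moved = frac @ op.rot_matrix.T + op.trans_vector + np.asarray(shift, dtype=float)
    orth = moved @ m.T
    return [replace(a, coords=tuple(xyz)) for a, xyz in zip(atoms, orth)]


def transform_residues(
    residues: list[ResidueRecord],
    op: SymOp,
    cell: UnitCell | None,
    shift: tuple[int, int, int] = (0, 0, 0),
) -> tuple[ResidueRecord, ...]:
    out = []
    for res in residues:
        out.append(replace(res, atoms=tuple(apply_symop(list(res.atoms), op, cell, shift))))
    return tuple(out)


def select_domain(model: StructureModel, domain: DomainAnnotation) -> list[ResidueRecord]:
    """Residues of the model covered by a domain annotation, in numbering order.

    Crystal structures routinely lack density for a few residues of a span, so
    the annotation is satisfied as long as at least one residue of the span is
    present; missing residues are simply absent from the returned list.
    """
    residues = [
        res
        for res in model.chains.get(domain.chain_id, [])
        if domain.contains(res.resnum)
    ]
    residues.sort(key=lambda r: (r.resnum, r.icode))
    if not residues:
        raise GeometryError(
            f"domain {domain.name}: no residues of chain {domain.chain_id} in span "
            f"{domain.start}-{domain.end}"
        )
    return residues


def _heavy_coords(residues) -> np.ndarray:
    pts = [a.xyz for res in residues for a in res.atoms if a.is_heavy]
    if not pts:
        raise GeometryError("no heavy atoms in residue set")
    return np.vstack(pts)


def generate_symmetry_mates(
    model: StructureModel,
    domain: DomainAnnotation,
    center: DomainAnnotation,
    shell: float,
) -> list[SymmetryMate]:
    """Enumerate symmetry images of ``domain`` near ``center``.

    Every non-identity combination of a space-group operator and a lattice
    translation in {-1,0,+1} per axis is applied to ``domain``; images with at
    least one heavy atom within ``shell`` Å of a heavy atom of ``center`` are
    returned, each carrying its generating operator and shift for provenance.
    The identity image (the deposited copy itself) is never returned.
    """
    if not model.cell_defined:
        raise GeometryError("cannot generate symmetry mates: unit cell undefined")
    if shell <= 0:
        raise GeometryError("shell radius must be positive")
    dom_res = select_domain(model, domain)
    cen_res = select_domain(model, center)
    tree = cKDTree(_heavy_coords(cen_res))

    mates: list[SymmetryMate] = []
    for op_index, op in enumerate(model.symops):
        for shift in itertools.product((-1, 0, 1), repeat=3):
            if op.is_identity and shift == (0, 0, 0):
                continue
            moved = transform_residues(dom_res, op, model.cell, shift)
            dists, _ = tree.query(_heavy_coords(moved), k=1)
            dmin = float(np.min(dists))
            if dmin <= shell:
                mates.append(
                    SymmetryMate(
                        op=op, op_index=op_index, shift=shift, residues=moved, min_distance=dmin
                    )
                )
    mates.sort(key=lambda m: (m.op_index, m.shift))
    return mates
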
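"""Reconstruction of the closed (inactive) two-domain assembly from a crystal.

In the inactive conformation of a classical PKC the C2 regulatory domain packs
against the catalytic domain, masking the interface.  Crystals of the enzyme
often contain this packing only *between* asymmetric units, so the inactive
model is rebuilt by searching the symmetry images of the catalytic domain for
the one that contacts the regulatory domain, docking that image, and deleting
the inter-domain linker.  The expected K205-E655-style salt bridge across the
interface serves as a validation handle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .interface import (
    CONTACT_CUTOFF,
    DEFAULT_N_POINTS,
    DEFAULT_PROBE,
    SALT_BRIDGE_CUTOFF,
    ContactPair,
    _salt_bridge_distance,
    compute_sasa,
    residue_contacts,
)
from .structure import (
    DomainAnnotation,
    ResidueRecord,
    StructureModel,
    UnitCell,
    generate_symmetry_mates,
    select_domain,
    write_pdb,
)

__all__ = ["InactiveAssembly", "NoAssembly", "build_inactive_model", "validate_contact",
           "write_assembly"]


@dataclass
class InactiveAssembly:
    """The reconstructed closed-conformation two-domain model with provenance."""

    regulatory_residues: tuple[ResidueRecord, ...]  # reference frame
    partner_residues: tuple[ResidueRecord, ...]  # symmetry-transformed copy
    operator_label: str
    operator_triplet: str
    lattice_shift: tuple[int, int, int]
    deleted_linker: tuple[int, int] | None
    contacts: list[ContactPair]
    buried_area: float
    n_operators_searched: int
    n_mates_contacting: int
    cell: UnitCell | None = None

    def __post_init__(self) -> None:
        if not self.contacts:
            raise GeometryError("an inactive assembly must have at least one inter-domain contact")

    @property
    def found(self) -> bool:
        return True

    def all_residues(self) -> list[ResidueRecord]:
        return list(self.regulatory_residues) + list(self.partner_residues)

    def find_residue(self, resid) -> ResidueRecord:
        """Locate a residue by ``(chain_id, resnum)``, ``"A:205"`` or plain resnum."""
        chain_id: str | None = None
        if isinstance(resid, str) and ":" in resid:
            chain_id, num = resid.split(":", 1)
            resnum = int(num)
        elif isinstance(resid, (tuple, list)):
            chain_id, resnum = resid[0], int(resid[1])
        else:
            resnum = int(resid)
        for res in self.all_residues():
            if res.resnum == resnum and (chain_id is None or res.chain_id == chain_id):
                return res
        raise GeometryError(f"residue {resid!r} not present in assembly")


@dataclass(frozen=True)
class NoAssembly:
    """Returned when no symmetry image of the partner touches the regulatory domain."""

    n_operators_searched: int
    n_images_tested: int

    @property
    def found(self) -> bool:
        return False


def _canonical(residues) -> tuple[ResidueRecord, ...]:
    """Sort residues and their atoms so the assembly is atom-order independent."""
    out = []
    for res in sorted(residues, key=lambda r: (r.chain_id, r.resnum, r.icode)):
        atoms = tuple(sorted(res.atoms, key=lambda a: (a.name, a.serial)))
        out.append(ResidueRecord(res.chain_id, res.resnum, res.icode, res.resname, atoms))
    return tuple(out)


def build_inactive_model(
    model: StructureModel,
    regulatory: DomainAnnotation,
    partner: DomainAnnotation,
    linker: tuple[int, int] | None = None,
    cutoff: float = CONTACT_CUTOFF,
    salt_bridge_cutoff: float = SALT_BRIDGE_CUTOFF,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> InactiveAssembly | NoAssembly:
    """Select the symmetry image of ``partner`` that docks onto ``regulatory``.

    All space-group images of the partner domain in the neighboring unit cells
    are screened for heavy-atom contact with the regulatory domain (kept in the
    reference frame; the two frame choices are related by a rigid motion, so
    every distance and ΔSASA is identical either way).  Among contacting
    images the one burying the largest interface area — ΔSASA summed over both
    sides — is selected; ties break deterministically by operator index, then
    lattice shift.  ``linker`` records the inter-domain connector span that is
    deleted from the model; it must not overlap either domain span.
    """
    if not model.cell_defined:
        raise GeometryError("cannot build inactive model: unit cell undefined")
    if linker is not None:
        lo, hi = linker
        if regulatory.overlaps(lo, hi) or partner.overlaps(lo, hi):
            raise GeometryError(
                f"linker span {lo}-{hi} overlaps a domain span; it must lie between domains"
            )

    reg_res = _canonical(select_domain(model, regulatory))
    mates = generate_symmetry_mates(model, partner, regulatory, shell=cutoff)
    n_images = len(model.symops) * 27 - 1

    best = None
    n_contacting = 0
    for mate in mates:
        mate_res = _canonical(mate.residues)
        contacts = residue_contacts(list(reg_res), list(mate_res), cutoff, salt_bridge_cutoff)
        if not contacts:
            continue
        n_contacting += 1
        open_area = compute_sasa(list(reg_res), probe, n_points).total + compute_sasa(
            list(mate_res), probe, n_points
        ).total
        closed_area = compute_sasa(list(reg_res) + list(mate_res), probe, n_points).total
        buried = open_area - closed_area
        key = (-buried, mate.op_index, mate.shift)
        if best is None or key < best[0]:
            best = (key, mate, mate_res, contacts, buried)

    if best is None:
        return NoAssembly(n_operators_searched=len(model.symops), n_images_tested=n_images)

    _, mate, mate_res, contacts, buried = best
    return InactiveAssembly(
        regulatory_residues=reg_res,
        partner_residues=mate_res,
        operator_label=mate.label,
        operator_triplet=mate.op.label,
        lattice_shift=mate.shift,
        deleted_linker=linker,
        contacts=contacts,
        buried_area=buried,
        n_operators_searched=len(model.symops),
        n_mates_contacting=n_contacting,
        cell=model.cell,
    )


def validate_contact(
    assembly: InactiveAssembly,
    res_a,
    res_b,
    cutoff: float = CONTACT_CUTOFF,
    salt_bridge_cutoff: float = SALT_BRIDGE_CUTOFF,
) -> tuple[float, bool, bool]:
    """Check an expected inter-residue contact in the assembly.

    Returns ``(min heavy-atom distance in Å, within cutoff?, salt bridge?)``.
    The distance is the brute-force minimum over all heavy-atom pairs.
    """
    ra = assembly.find_residue(res_a)
    rb = assembly.find_residue(res_b)
    dmin = min(
        float(np.linalg.norm(a.xyz - b.xyz))
        for a in ra.heavy_atoms()
        for b in rb.heavy_atoms()
    )
    sb = _salt_bridge_distance(ra, rb)
    return dmin, dmin <= cutoff, sb is not None and sb <= salt_bridge_cutoff


def write_assembly(assembly: InactiveAssembly, pdb_path, provenance_path) -> None:
    """Write the assembly as a two-chain PDB plus a JSON provenance side-car.

    The transformed partner copy is re-lettered to the next free chain id if it
    collides with the regulatory chain.
    """
    reg = list(assembly.regulatory_residues)
    par = list(assembly.partner_residues)
    reg_chain = reg[0].chain_id
    par_chain = par[0].chain_id
    if par_chain == reg_chain:
        for cand in "BCDEFGHIJKLMNOPQRSTUVWXYZA":
            if cand != reg_chain:
                par_chain = cand
                break
        par = [
            ResidueRecord(par_chain, r.resnum, r.icode, r.resname, r.atoms) for r in par
        ]
    text = write_pdb(reg + par, cell=assembly.cell)
    with open(pdb_path, "w") as fh:
        fh.write(text)
    provenance = {
        "operator_triplet": assembly.operator_triplet,
        "lattice_shift": list(assembly.lattice_shift),
        "deleted_linker": list(assembly.deleted_linker) if assembly.deleted_linker else None,
        "regulatory_chain": reg_chain,
        "partner_chain_in_pdb": par_chain,
        "partner_chain_original": assembly.partner_residues[0].chain_id,
        "buried_area_A2": assembly.buried_area,
        "n_operators_searched": assembly.n_operators_searched,
        "n_mates_contacting": assembly.n_mates_contacting,
        "contacts": [
            {
                "res_a": list(c.res_a),
                "res_b": list(c.res_b),
                "resname_a": c.resname_a,
                "resname_b": c.resname_b,
                "min_distance_A": round(c.min_distance, 4),
                "salt_bridge": c.is_salt_bridge,
            }
            for c in assembly.contacts
        ],
    }
    with open(provenance_path, "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
        fh.write("\n")
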
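"""Inter-domain contacts and solvent accessibility (Shrake-Rupley SASA).

The epitope-selection criterion — a peptide exposed only in the active kinase —
is made quantitative here as ΔSASA: the solvent-accessible surface area a
residue loses when the regulatory domain packs against the catalytic domain.
SASA is computed with the Shrake-Rupley sphere-point method on a deterministic
golden-spiral point lattice, so results are bit-reproducible and an isolated
atom scores exactly 4π(r + probe)².
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import EpistateError, GeometryError
from .structure import Atom3D, DomainAnnotation, ResidueRecord

__all__ = [
    "VDW_RADII",
    "MAX_RESIDUE_SASA",
    "ContactPair",
    "ExposureProfile",
    "ResidueExposure",
    "sasa_per_atom",
    "compute_sasa",
    "residue_contacts",
    "exposure_profile",
]

# Heavy-atom van der Waals radii (Å); hydrogens are excluded throughout.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

DEFAULT_PROBE = 1.4
DEFAULT_N_POINTS = 960
CONTACT_CUTOFF = 4.5
SALT_BRIDGE_CUTOFF = 4.0

# Maximal per-residue SASA in a Gly-X-Gly tripeptide (Å², theoretical values
# of Tien et al. 2013), used to normalize absolute SASA to relative exposure.
MAX_RESIDUE_SASA: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

_BASIC_SIDECHAIN_N = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}
_ACIDIC_SIDECHAIN_O = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}


def unit_sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = i * math.pi * (3.0 - math.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _radii_for(atoms: list[Atom3D]) -> np.ndarray:
    radii = np.empty(len(atoms))
    for i, atom in enumerate(atoms):
        try:
            radii[i] = VDW_RADII[atom.element.upper()]
        except KeyError:
            raise EpistateError(
                f"unknown element {atom.element!r} for atom {atom.name} "
                f"(serial {atom.serial}); known elements: {', '.join(sorted(VDW_RADII))}"
            ) from None
    return radii


def sasa_per_atom(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> np.ndarray:
    """Shrake-Rupley SASA (Å²) for each sphere.

    A lattice of ``n_points`` test points is placed on each atom's solvent
    sphere of radius r_i + probe; a point is accessible if it lies outside
    every neighbor's solvent sphere.  SASA_i = (accessible fraction) x
    4π(r_i + probe)².  Deterministic: the point lattice is fixed.
    """
    if n_points < 92:
        raise ValueError("n_points must be >= 92")
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    sphere = unit_sphere_points(n_points)
    expanded = np.asarray(radii, dtype=float) + probe
    tree = cKDTree(coords)
    max_reach = 2.0 * float(np.max(expanded))
    out = np.empty(n)
    for i in range(n):
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        pts = coords[i] + expanded[i] * sphere
        if neighbors:
            nb = np.array(neighbors)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (expanded[nb] ** 2)[None, :]).any(axis=1)
            exposed = n_points - int(buried.sum())
        else:
            exposed = n_points
        out[i] = exposed / n_points * 4 * math.pi * expanded[i] ** 2
    return out


@dataclass(frozen=True)
class SasaResult:
    per_atom: np.ndarray  # aligned with the heavy atoms of the input residues
    per_residue: dict[tuple[str, int, str], float]

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def compute_sasa(
    residues: list[ResidueRecord],
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> SasaResult:
    """Per-atom and per-residue SASA of a residue set (heavy atoms only)."""
    heavy: list[Atom3D] = []
    owner: list[tuple[str, int, str]] = []
    for res in residues:
        for atom in res.heavy_atoms():
            heavy.append(atom)
            owner.append(res.key)
    if not heavy:
        raise GeometryError("no heavy atoms to compute SASA for")
    coords = np.array([a.coords for a in heavy])
    per_atom = sasa_per_atom(coords, _radii_for(heavy), probe, n_points)
    per_residue: dict[tuple[str, int, str], float] = {res.key: 0.0 for res in residues}
    for key, s in zip(owner, per_atom):
        per_residue[key] += float(s)
    return SasaResult(per_atom=per_atom, per_residue=per_residue)


# --------------------------------------------------------------------------
# Contacts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactPair:
    res_a: tuple[str, int, str]
    res_b: tuple[str, int, str]
    resname_a: str
    resname_b: str
    min_distance: float
    is_salt_bridge: bool

    def __str__(self) -> str:
        tag = " salt-bridge" if self.is_salt_bridge else ""
        return (
            f"{self.res_a[0]}:{self.resname_a}{self.res_a[1]} -- "
            f"{self.res_b[0]}:{self.resname_b}{self.res_b[1]} "
            f"{self.min_distance:.2f} A{tag}"
        )


def _salt_bridge_distance(ra: ResidueRecord, rb: ResidueRecord) -> float | None:
    """Min N-O distance between charged side-chain groups, or None if not a K/R/H vs D/E pair."""
    for basic, acidic in ((ra, rb), (rb, ra)):
        n_names = _BASIC_SIDECHAIN_N.get(basic.resname)
        o_names = _ACIDIC_SIDECHAIN_O.get(acidic.resname)
        if n_names is None or o_names is None:
            continue
        n_atoms = [a for a in basic.atoms if a.name in n_names]
        o_atoms = [a for a in acidic.atoms if a.name in o_names]
        if not n_atoms or not o_atoms:
            continue
        return min(
            float(np.linalg.norm(na.xyz - oa.xyz)) for na in n_atoms for oa in o_atoms
        )
    return None


def residue_contacts(
    dom_a: list[ResidueRecord],
    dom_b: list[ResidueRecord],
    cutoff: float = CONTACT_CUTOFF,
    salt_bridge_cutoff: float = SALT_BRIDGE_CUTOFF,
) -> list[ContactPair]:
    """All residue pairs across two domains with min heavy-atom distance <= cutoff.

    Sorted by distance (ties by residue identifiers).  A pair is flagged as a
    salt bridge when a Lys/Arg/His side-chain nitrogen sits within
    ``salt_bridge_cutoff`` Å of an Asp/Glu side-chain oxygen.
    """
    if cutoff <= 0:
        raise GeometryError("contact cutoff must be positive")
    if not dom_a or not dom_b:
        raise GeometryError("both residue sets must be non-empty")

    coords_a, idx_a = [], []
    for i, res in enumerate(dom_a):
        for atom in res.heavy_atoms():
            coords_a.append(atom.xyz)
            idx_a.append(i)
    coords_b, idx_b = [], []
    for j, res in enumerate(dom_b):
        for atom in res.heavy_atoms():
            coords_b.append(atom.xyz)
            idx_b.append(j)

    tree_a = cKDTree(np.vstack(coords_a))
    tree_b = cKDTree(np.vstack(coords_b))
    best: dict[tuple[int, int], float] = {}
    pairs = tree_a.sparse_distance_matrix(tree_b, cutoff, output_type="coo_matrix")
    for ai, bi, d in zip(pairs.row, pairs.col, pairs.data):
        key = (idx_a[ai], idx_b[bi])
        if d < best.get(key, math.inf):
            best[key] = float(d)

    out = []
    for (i, j), dist in best.items():
        ra, rb = dom_a[i], dom_b[j]
        sb = _salt_bridge_distance(ra, rb)
        out.append(
            ContactPair(
                res_a=ra.key,
                res_b=rb.key,
                resname_a=ra.resname,
                resname_b=rb.resname,
                min_distance=dist,
                is_salt_bridge=sb is not None and sb <= salt_bridge_cutoff,
            )
        )
    out.sort(key=lambda p: (p.min_distance, p.res_a, p.res_b))
    return out


# --------------------------------------------------------------------------
# Exposure profiles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidueExposure:
    chain_id: str
    resnum: int
    icode: str
    resname: str
    sasa_open: float
    sasa_closed: float
    delta_sasa: float
    rel_exposure_open: float | None  # None when the residue type has no reference area


@dataclass
class ExposureProfile:
    """Per-residue SASA in the open (isolated domain) and closed (assembly) states."""

    domain_name: str
    sites: dict[tuple[str, int, str], ResidueExposure]

    def residue_numbers(self) -> list[int]:
        return sorted(site.resnum for site in self.sites.values())

    def by_resnum(self, resnum: int) -> ResidueExposure:
        for site in self.sites.values():
            if site.resnum == resnum:
                return site
        raise KeyError(resnum)

    @property
    def total_delta(self) -> float:
        return sum(site.delta_sasa for site in self.sites.values())

    def to_tsv(self) -> str:
        lines = ["chain\tresnum\tresname\tsasa_open\tsasa_closed\tdelta_sasa\trel_exposure_open"]
        for key in sorted(self.sites):
            s = self.sites[key]
            rel = "NA" if s.rel_exposure_open is None else f"{s.rel_exposure_open:.4f}"
            lines.append(
                f"{s.chain_id}\t{s.resnum}\t{s.resname}\t{s.sasa_open:.4f}\t"
                f"{s.sasa_closed:.4f}\t{s.delta_sasa:.4f}\t{rel}"
            )
        return "\n".join(lines) + "\n"


def exposure_profile(
    assembly,
    domain: DomainAnnotation,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_N_POINTS,
) -> ExposureProfile:
    """ΔSASA profile of one domain of a two-domain assembly.

    ``sasa_open`` is computed on the domain's atoms alone (the activated,
    dissociated state); ``sasa_closed`` on the full assembly.  Their difference
    is the burial each residue suffers in the closed conformation — it is
    non-negative (to numerical tolerance) and concentrated at the interface.
    """
    reg = list(assembly.regulatory_residues)
    par = list(assembly.partner_residues)
    if reg and reg[0].chain_id == domain.chain_id and any(domain.contains(r.resnum) for r in reg):
        own, other = reg, par
    elif par and par[0].chain_id == domain.chain_id and any(domain.contains(r.resnum) for r in par):
        own, other = par, reg
    else:
        raise GeometryError(f"domain {domain.name} not found in assembly")
    own = [r for r in own if domain.contains(r.resnum)]

    open_sasa = compute_sasa(own, probe, n_points)
    closed_sasa = compute_sasa(own + other, probe, n_points)

    sites: dict[tuple[str, int, str], ResidueExposure] = {}
    for res in own:
        so = open_sasa.per_residue[res.key]
        sc = closed_sasa.per_residue[res.key]
        ref = MAX_RESIDUE_SASA.get(res.resname)
        rel = None if ref is None else min(1.0, so / ref)
        sites[res.key] = ResidueExposure(
            chain_id=res.chain_id,
            resnum=res.resnum,
            icode=res.icode,
            resname=res.resname,
            sasa_open=so,
            sasa_closed=sc,
            delta_sasa=so - sc,
            rel_exposure_open=rel,
        )
    return ExposureProfile(domain_name=domain.name, sites=sites)
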
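"""Synthetic fixtures with the geometric and statistical structure the pipeline assumes.

Three generators mirror the three kinds of real input:

* a *toy crystal* — two poly-alanine domains in a P1 cell, far apart in the
  deposited frame, where exactly one lattice translation of the second domain
  docks onto the first through a planted Lys-Glu salt bridge (the
  "neighboring asymmetric unit" situation the model builder must recover);
* a *toy family alignment* — target-family sequences conserved inside a
  planted window and noisy outside it, off-target sequences divergent inside
  the window (the conservation pattern a family-restricted epitope shows);
* a *synthetic IHC cohort* — per-sample staining positivity scores for an
  ER-positive baseline cohort and a mean-shifted triple-negative cohort, with
  optional intensity images whose pixel mean encodes each score.

Every generator is seed-deterministic and self-validates its planted ground
truth before returning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError, EpistateError
from .structure import (
    Atom3D,
    DomainAnnotation,
    ResidueRecord,
    UnitCell,
    generate_symmetry_mates,
    parse_structure,
    write_pdb,
)
from .interface import CONTACT_CUTOFF, SALT_BRIDGE_CUTOFF, residue_contacts
from .conservation import AlignedSequence, AlignmentSet, conservation_profile, window_scores
from .ihc import IntensityImage

__all__ = [
    "ToyCrystalSpec",
    "ToyAlignmentSpec",
    "CohortSpec",
    "make_toy_crystal",
    "make_toy_alignment",
    "simulate_cohort",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


# --------------------------------------------------------------------------
# Toy crystal
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyCrystalSpec:
    """Two chains in a P1 cell touching only through a lattice translation.

    Chain A (regulatory) runs along y at x ≈ ``x_backbone``; chain B (partner)
    is offset by ``gap`` Å in x, out of contact range in the reference frame.
    The planted Lys (chain A) and Glu (chain B) side-chain surrogates point
    toward each other across the cell boundary, so the B copy translated by
    -a lands its carboxylate ``cell.a - gap - 6`` Å from the ammonium group.
    """

    cell: tuple[float, float, float] = (30.0, 50.0, 20.0)
    spacegroup: str = "P 1"
    n_res_a: int = 20
    n_res_b: int = 20
    planted_a: int = 10  # residue number of the Lys on chain A
    planted_b: int = 10  # residue number of the Glu on chain B
    gap: float = 21.0  # reference-frame x offset between the backbones, Å
    residue_spacing: float = 2.0  # Å along y
    x_backbone: float = 4.0
    sidechain_reach: float = 3.0

    @property
    def planted_distance(self) -> float:
        return self.cell[0] - self.gap - 2 * self.sidechain_reach

    def __post_init__(self) -> None:
        if self.n_res_a < 1 or self.n_res_b < 1:
            raise GeometryError("domains must have at least one residue")
        if not 1 <= self.planted_a <= self.n_res_a or not 1 <= self.planted_b <= self.n_res_b:
            raise GeometryError("planted residue index outside its domain")
        d = self.planted_distance
        if not 0.5 <= d <= SALT_BRIDGE_CUTOFF:
            raise GeometryError(
                f"spec is geometrically unsatisfiable: planted contact distance would be "
                f"{d:.1f} Å (cell a={self.cell[0]}, gap={self.gap}); it must lie in "
                f"[0.5, {SALT_BRIDGE_CUTOFF}] Å"
            )


def _toy_chain(
    chain_id: str,
    n_res: int,
    x0: float,
    spacing: float,
    planted: int,
    planted_resname: str,
    sidechain: tuple[str, float],
    serial0: int,
) -> list[ResidueRecord]:
    """Poly-alanine backbone surrogate (N, CA, C per residue) along y, with one
    charged side-chain atom on the planted residue."""
    residues = []
    serial = serial0
    sc_name, sc_x = sidechain
    for i in range(1, n_res + 1):
        y = 2.0 + spacing * (i - 1)
        atoms = []
        for name, dx, element in (("N", -0.3, "N"), ("CA", 0.0, "C"), ("C", 0.3, "C")):
            serial += 1
            atoms.append(Atom3D(serial=serial, name=name, element=element,
                                coords=(x0 + dx, y, 5.0)))
        resname = "ALA"
        if i == planted:
            resname = planted_resname
            serial += 1
            atoms.append(Atom3D(serial=serial, name=sc_name,
                                element=sc_name[0], coords=(sc_x, y, 5.0)))
        residues.append(ResidueRecord(chain_id, i, " ", resname, tuple(atoms)))
    return residues


def make_toy_crystal(spec: ToyCrystalSpec | None = None) -> tuple[str, dict]:
    """Generate the toy crystal as PDB text plus a ground-truth side-car.

    The side-car records the generating operator, lattice shift and planted
    interface pair; the planted invariants (no reference-frame contact, exactly
    one contacting mate, planted pair within salt-bridge range) are checked by
    actually running the symmetry search before the text is returned.
    """
    spec = spec or ToyCrystalSpec()
    a, b, c = spec.cell
    cell = UnitCell(a, b, c, 90.0, 90.0, 90.0)
    x_a = spec.x_backbone
    x_b = spec.x_backbone + spec.gap
    chain_a = _toy_chain("A", spec.n_res_a, x_a, spec.residue_spacing, spec.planted_a,
                         "LYS", ("NZ", x_a - spec.sidechain_reach), serial0=0)
    chain_b = _toy_chain("B", spec.n_res_b, x_b, spec.residue_spacing, spec.planted_b,
                         "GLU", ("OE1", x_b + spec.sidechain_reach),
                         serial0=4 * spec.n_res_a)
    pdb_text = write_pdb(chain_a + chain_b, cell=cell, spacegroup=spec.spacegroup)

    # Self-validate the planted ground truth on the generated text.
    model = parse_structure(pdb_text)
    ref_contacts = residue_contacts(
        [r for ch in ("A",) for r in model.chains[ch]],
        list(model.chains["B"]),
        CONTACT_CUTOFF,
    )
    if ref_contacts:
        raise GeometryError("spec invalid: domains touch already in the reference frame")
    dom_a = DomainAnnotation("regulatory", "A", 1, spec.n_res_a)
    dom_b = DomainAnnotation("partner", "B", 1, spec.n_res_b)
    mates = generate_symmetry_mates(model, dom_b, dom_a, shell=CONTACT_CUTOFF)
    if len(mates) != 1 or mates[0].shift != (-1, 0, 0):
        raise GeometryError(
            f"spec invalid: expected exactly one contacting mate at shift (-1,0,0), "
            f"found {[(m.op.label, m.shift) for m in mates]}"
        )
    planted_pairs = [
        p for p in residue_contacts(list(model.chains["A"]), list(mates[0].residues))
        if p.res_a == ("A", spec.planted_a, " ") and p.res_b == ("B", spec.planted_b, " ")
    ]
    if not planted_pairs or not planted_pairs[0].is_salt_bridge:
        raise GeometryError("spec invalid: planted pair is not a salt bridge in the mate frame")

    truth = {
        "operator_triplet": mates[0].op.label,
        "lattice_shift": list(mates[0].shift),
        "interface_pair": {
            "regulatory": ["A", spec.planted_a, "LYS"],
            "partner": ["B", spec.planted_b, "GLU"],
            "distance_A": round(planted_pairs[0].min_distance, 4),
        },
        "regulatory_domain": ["A", 1, spec.n_res_a],
        "partner_domain": ["B", 1, spec.n_res_b],
    }
    return pdb_text, truth


# --------------------------------------------------------------------------
# Toy alignment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyAlignmentSpec:
    n_target: int = 6
    n_offtarget: int = 2
    length: int = 20
    window: tuple[int, int] = (8, 12)  # inclusive, reference numbering from `offset`
    p_background: float = 0.35  # substitution probability outside the window
    p_offtarget_window: float = 0.8  # off-target substitution probability inside it
    offset: int = 1
    base_sequence: str | None = None  # defaults to a random sequence
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_background, self.p_offtarget_window):
            if not 0.0 <= p <= 1.0:
                raise EpistateError("substitution probabilities must lie in [0, 1]")
        lo, hi = self.window
        if not self.offset <= lo <= hi <= self.offset + self.length - 1:
            raise EpistateError("planted window must lie within the sequence")
        if self.n_target < 2:
            raise EpistateError("need at least two target sequences")
        if self.base_sequence is not None and len(self.base_sequence) != self.length:
            raise EpistateError("base_sequence length must equal `length`")


def _mutate(seq: list[str], positions, prob: float, rng: np.random.Generator) -> None:
    for i in positions:
        if rng.random() < prob:
            choices = [c for c in AMINO_ACIDS if c != seq[i]]
            seq[i] = choices[rng.integers(len(choices))]


def make_toy_alignment(spec: ToyAlignmentSpec | None = None) -> tuple[str, dict]:
    """Generate a gapless FASTA alignment with a planted conserved window.

    Target sequences are identical inside the window and mutated with
    probability ``p_background`` outside it; off-target sequences are mutated
    inside the window with probability ``p_offtarget_window`` (and with the
    background rate outside).  The first target sequence is the unmutated
    reference.  Before returning, the planted window is verified to have mean
    target conservation at least as high as every other equal-length window.
    """
    spec = spec or ToyAlignmentSpec()
    rng = np.random.default_rng(spec.seed)
    if spec.base_sequence is None:
        base = [AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=spec.length)]
    else:
        base = list(spec.base_sequence.upper())
    lo, hi = spec.window
    win_idx = range(lo - spec.offset, hi - spec.offset + 1)
    out_idx = [i for i in range(spec.length) if not (lo - spec.offset <= i <= hi - spec.offset)]

    records: list[tuple[str, str, str]] = []  # (id, family, seq)
    records.append(("target_1", "target", "".join(base)))
    for k in range(2, spec.n_target + 1):
        seq = list(base)
        _mutate(seq, out_idx, spec.p_background, rng)
        records.append((f"target_{k}", "target", "".join(seq)))
    for k in range(1, spec.n_offtarget + 1):
        seq = list(base)
        _mutate(seq, win_idx, spec.p_offtarget_window, rng)
        _mutate(seq, out_idx, spec.p_background, rng)
        records.append((f"offtarget_{k}", "offtarget", "".join(seq)))

    aln = AlignmentSet(
        sequences=[AlignedSequence(i, f, s) for i, f, s in records],
        reference_id="target_1",
        offset=spec.offset,
    )
    profile = conservation_profile(aln)
    win_cons, _, _ = window_scores(profile, spec.window)
    width = hi - lo + 1
    last_start = spec.offset + spec.length - width
    for start in range(spec.offset, last_start + 1):
        if start == lo:
            continue
        other, _, _ = window_scores(profile, (start, start + width - 1))
        if other > win_cons + 1e-12:
            raise EpistateError(
                f"generated alignment violates the planted ground truth: window "
                f"({start},{start + width - 1}) is more conserved than the planted one"
            )

    fasta = "".join(f">{rid}\n{seq}\n" for rid, _, seq in records)
    truth = {
        "window": [lo, hi],
        "families": {rid: fam for rid, fam, _ in records},
        "reference_id": "target_1",
        "offset": spec.offset,
        "window_mean_conservation": win_cons,
    }
    return fasta, truth


# --------------------------------------------------------------------------
# IHC cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Cohort sizes follow the tissue-microarray study design (105 ER+ vs 29
    triple-negative); the triple-negative positivity mean is shifted upward by
    ``delta`` (default 1.5 SD — at these n the expected two-sample t is ≈7, so
    the p < 1e-4 headline comparison is robustly reproducible)."""

    n_er: int = 105
    n_tn: int = 29
    mu0: float = 80.0  # ER+ baseline mean positivity score
    sigma: float = 20.0  # common SD of per-sample scores
    delta: float = 30.0  # TN mean shift (1.5 sigma)
    image_shape: tuple[int, int] | None = None  # e.g. (32, 32) to also emit images
    pixel_noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_er < 2 or self.n_tn < 2:
            raise EpistateError("each cohort needs at least two samples")
        if self.sigma <= 0:
            raise EpistateError("score SD must be positive")


SCORE_MIN, SCORE_MAX = 1.0, 256.0


def simulate_cohort(
    spec: CohortSpec | None = None,
) -> tuple[pd.DataFrame, dict[str, IntensityImage] | None]:
    """Draw per-sample positivity scores (and optionally matching images).

    Scores are normal(mu0, sigma) for the ER+ cohort and normal(mu0+delta,
    sigma) for the triple-negative cohort, truncated to the valid score range
    (1, 256].  When ``image_shape`` is set, each sample also receives an 8-bit
    intensity image whose pixels are drawn around 256 - score, so quantifying
    the image recovers the score to within a fraction of an intensity unit.
    """
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    er = rng.normal(spec.mu0, spec.sigma, size=spec.n_er)
    tn = rng.normal(spec.mu0 + spec.delta, spec.sigma, size=spec.n_tn)
    scores = np.clip(np.concatenate([er, tn]), SCORE_MIN, SCORE_MAX)
    ids = [f"ER_{i:03d}" for i in range(1, spec.n_er + 1)] + [
        f"TN_{i:03d}" for i in range(1, spec.n_tn + 1)
    ]
    labels = ["ER+"] * spec.n_er + ["triple-negative"] * spec.n_tn
    table = pd.DataFrame({"sample_id": ids, "cohort": labels, "score": scores})

    images = None
    if spec.image_shape is not None:
        images = {}
        for sid, score in zip(ids, scores):
            mean_intensity = 256.0 - score
            pix = rng.normal(mean_intensity, spec.pixel_noise_sd, size=spec.image_shape)
            images[sid] = IntensityImage(np.rint(pix).clip(0, 255).astype(np.uint8))
    return table, images
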
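"""Family-conservation scoring of alignment columns, mapped to structure numbering.

A usable state-specific epitope must be shared by every isoform the antibody
should recognize (the target family, e.g. classical PKC α/βΙ/βΙΙ/γ) and absent
from the isoforms it must not recognize (the off-target family, e.g. novel PKC
δ/ε).  Given a multiple alignment with family labels, this module scores each
column by consensus-match fraction within the target family and by divergence
of the off-target family from that consensus, and maps columns to the residue
numbering of a reference sequence so the scores can be joined with structural
exposure profiles.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from io import StringIO

from Bio import AlignIO

from .errors import EpistateError, ParseError

__all__ = [
    "AlignedSequence",
    "AlignmentSet",
    "ConservationSite",
    "ConservationProfile",
    "load_alignment",
    "conservation_profile",
    "window_scores",
]

GAP_CHARS = "-."


@dataclass(frozen=True)
class AlignedSequence:
    id: str
    family: str  # "target" | "offtarget"
    seq: str


@dataclass
class AlignmentSet:
    sequences: list[AlignedSequence]
    reference_id: str
    offset: int = 1  # structure residue number of the reference's first residue

    def __post_init__(self) -> None:
        widths = {len(s.seq) for s in self.sequences}
        if len(widths) != 1:
            raise ParseError(f"aligned sequences have unequal lengths: {sorted(widths)}")
        for s in self.sequences:
            if s.family not in ("target", "offtarget"):
                raise EpistateError(f"sequence {s.id}: family must be target/offtarget")
        if len(self.targets) < 2:
            raise EpistateError("at least two target-family sequences are required")
        ref = [s for s in self.sequences if s.id == self.reference_id]
        if not ref:
            raise EpistateError(f"reference sequence {self.reference_id!r} not in alignment")
        if ref[0].family != "target":
            raise EpistateError("the reference sequence must belong to the target family")

    @property
    def width(self) -> int:
        return len(self.sequences[0].seq)

    @property
    def targets(self) -> list[AlignedSequence]:
        return [s for s in self.sequences if s.family == "target"]

    @property
    def offtargets(self) -> list[AlignedSequence]:
        return [s for s in self.sequences if s.family == "offtarget"]

    @property
    def reference(self) -> AlignedSequence:
        return next(s for s in self.sequences if s.id == self.reference_id)


def load_alignment(
    text: str,
    family_map: dict[str, str],
    reference_id: str,
    offset: int = 1,
) -> AlignmentSet:
    """Load a FASTA or Clustal alignment and attach family labels.

    The format is sniffed from the header line.  Every sequence id must appear
    in ``family_map`` with value ``"target"`` or ``"offtarget"``.
    """
    fmt = "clustal" if text.lstrip().upper().startswith("CLUSTAL") else "fasta"
    try:
        aln = AlignIO.read(StringIO(text), fmt)
    except ValueError as exc:
        raise ParseError(f"cannot read {fmt} alignment: {exc}") from exc
    sequences = []
    for rec in aln:
        if rec.id not in family_map:
            raise EpistateError(f"sequence {rec.id!r} has no family label")
        sequences.append(AlignedSequence(id=rec.id, family=family_map[rec.id], seq=str(rec.seq)))
    return AlignmentSet(sequences=sequences, reference_id=reference_id, offset=offset)


@dataclass(frozen=True)
class ConservationSite:
    resnum: int
    column: int  # 0-based alignment column
    consensus: str
    target_conservation: float | None  # None when undefined (all targets gapped)
    offtarget_divergence: float | None  # None when no off-target sequences


@dataclass
class ConservationProfile:
    sites: dict[int, ConservationSite]  # keyed by reference residue number

    def residue_numbers(self) -> list[int]:
        return sorted(self.sites)

    def defined(self, resnum: int) -> bool:
        site = self.sites.get(resnum)
        return site is not None and site.target_conservation is not None


def _entropy_conservation(counts: Counter, n_total: int) -> float:
    """1 - normalized Shannon entropy over the 20 amino-acid alphabet; gaps count
    as one extra mismatch symbol."""
    probs = [c / n_total for c in counts.values() if c > 0]
    h = -sum(p * math.log(p) for p in probs)
    return max(0.0, 1.0 - h / math.log(20))


def conservation_profile(aln: AlignmentSet, metric: str = "consensus") -> ConservationProfile:
    """Score every reference non-gap column of the alignment.

    consensus  = modal residue among target-family non-gap symbols (ties broken
                 alphabetically); target_conservation = fraction of target
                 sequences matching it, a gap counting as a mismatch (an indel
                 destroys a linear epitope); offtarget_divergence = fraction of
                 off-target sequences NOT matching the consensus, or None when
                 the alignment has no off-target family.
    ``metric="entropy"`` replaces the conservation score by 1 - normalized
    Shannon entropy of the target column; consensus and divergence are
    unchanged.
    """
    if metric not in ("consensus", "entropy"):
        raise EpistateError(f"unknown conservation metric {metric!r}")
    targets = aln.targets
    offtargets = aln.offtargets
    ref = aln.reference
    sites: dict[int, ConservationSite] = {}
    resnum = aln.offset - 1
    for col in range(aln.width):
        if ref.seq[col] in GAP_CHARS:
            continue
        resnum += 1
        symbols = [s.seq[col].upper() for s in targets]
        non_gap = [c for c in symbols if c not in GAP_CHARS]
        if not non_gap:
            sites[resnum] = ConservationSite(resnum, col, "-", None, None)
            continue
        counts = Counter(non_gap)
        top = max(counts.values())
        consensus = min(c for c, n in counts.items() if n == top)
        if metric == "consensus":
            cons = sum(1 for c in symbols if c == consensus) / len(symbols)
        else:
            cons = _entropy_conservation(Counter(symbols), len(symbols))
        if offtargets:
            div = sum(1 for s in offtargets if s.seq[col].upper() != consensus) / len(offtargets)
        else:
            div = None
        sites[resnum] = ConservationSite(resnum, col, consensus, cons, div)
    return ConservationProfile(sites=sites)


def window_scores(
    profile: ConservationProfile, span: tuple[int, int]
) -> tuple[float, float | None, int]:
    """Mean conservation and off-target divergence over an inclusive residue span.

    Returns ``(mean target_conservation, mean offtarget_divergence or None,
    number of undefined positions in the span)``.  Undefined positions (gapped
    columns or residues outside the profile) are excluded from the means.
    """
    lo, hi = span
    cons, divs, undef = [], [], 0
    for resnum in range(lo, hi + 1):
        site = profile.sites.get(resnum)
        if site is None or site.target_conservation is None:
            undef += 1
            continue
        cons.append(site.target_conservation)
        if site.offtarget_divergence is not None:
            divs.append(site.offtarget_divergence)
    if not cons:
        raise EpistateError(f"span {lo}-{hi}: no defined conservation positions")
    mean_cons = sum(cons) / len(cons)
    mean_div = sum(divs) / len(divs) if divs else None
    return mean_cons, mean_div, undef
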
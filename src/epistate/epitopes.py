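"""Sliding-window epitope ranking on the regulatory domain.

A good activation-state-specific epitope satisfies four criteria at once: it
is buried by the partner domain in the closed (inactive) assembly, well
exposed on the isolated (active-like) domain, conserved across the target
family, and divergent in the off-target family.  Each peptide-length window is
scored on all four in [0, 1] and ranked by a weighted geometric mean — the
criteria are conjunctive, so a window failing any one of them scores zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio.SeqUtils import seq1

from .conservation import ConservationProfile
from .errors import EpistateError
from .interface import ExposureProfile

__all__ = ["CandidateEpitope", "ScanResult", "scan_epitopes", "annotate_motif"]

DEFAULT_WINDOW = 15  # length of the C2Cat immunogen peptide
DEFAULT_WEIGHTS = (1.0, 1.0, 1.0, 1.0)  # burial, exposure, conservation, divergence


@dataclass(frozen=True)
class CandidateEpitope:
    span: tuple[int, int]  # inclusive residue-number range
    sequence: str
    burial_closed: float
    exposure_open: float
    conservation: float
    divergence: float | None
    composite: float
    rank: int

    def __post_init__(self) -> None:
        if len(self.sequence) != self.span[1] - self.span[0] + 1:
            raise EpistateError("candidate sequence length does not match its span")


@dataclass
class ScanResult:
    candidates: list[CandidateEpitope]  # sorted by rank
    skipped: list[tuple[tuple[int, int], str]]  # (span, reason), never silently dropped
    window: int
    weights: tuple[float, float, float, float]

    @property
    def top(self) -> CandidateEpitope:
        return self.candidates[0]

    def to_tsv(self) -> str:
        lines = ["rank\tstart\tend\tsequence\tburial_closed\texposure_open\t"
                 "conservation\tdivergence\tcomposite"]
        for c in self.candidates:
            div = "NA" if c.divergence is None else f"{c.divergence:.4f}"
            lines.append(
                f"{c.rank}\t{c.span[0]}\t{c.span[1]}\t{c.sequence}\t{c.burial_closed:.4f}\t"
                f"{c.exposure_open:.4f}\t{c.conservation:.4f}\t{div}\t{c.composite:.4f}"
            )
        return "\n".join(lines) + "\n"


def _geometric_mean(components: list[tuple[float, float]]) -> float:
    """Weighted geometric mean of (value, weight) pairs; zero if any value is 0."""
    wsum = sum(w for _, w in components)
    if wsum == 0:
        raise EpistateError("at least one component weight must be positive")
    if any(v == 0.0 for v, w in components if w > 0):
        return 0.0
    return math.exp(sum(w * math.log(v) for v, w in components if w > 0) / wsum)


def _arithmetic_mean(components: list[tuple[float, float]]) -> float:
    wsum = sum(w for _, w in components)
    return sum(v * w for v, w in components) / wsum


def scan_epitopes(
    exposure: ExposureProfile,
    conservation: ConservationProfile,
    window: int = DEFAULT_WINDOW,
    weights: tuple[float, float, float, float] = DEFAULT_WEIGHTS,
    composite: str = "geometric",
) -> ScanResult:
    """Score and rank every peptide window of the profiled domain.

    Per-window components, each in [0, 1]:

    * ``burial_closed`` — mean over residues of ΔSASA / SASA_open (fraction of
      open-state exposure lost on assembly; 0 for residues with no open SASA);
    * ``exposure_open`` — mean relative open-state exposure;
    * ``conservation`` — mean target-family conservation;
    * ``divergence`` — mean off-target divergence, or None when the alignment
      carried no off-target family (the component is then left out of the
      composite rather than defaulting).

    Candidates are sorted by composite descending; ties break toward the
    N-terminal-most span.  Windows containing any undefined position are
    reported in ``skipped`` with a reason, never silently dropped.
    """
    if window < 5:
        raise EpistateError("window must be at least 5 residues")
    if composite not in ("geometric", "arithmetic"):
        raise EpistateError(f"unknown composite rule {composite!r}")
    combine = _geometric_mean if composite == "geometric" else _arithmetic_mean

    resnums = exposure.residue_numbers()
    if window > len(resnums):
        raise EpistateError(
            f"window {window} exceeds the profiled domain length {len(resnums)}"
        )
    lo, hi = resnums[0], resnums[-1]
    exp_sites = {s.resnum: s for s in exposure.sites.values()}

    scored = []
    skipped: list[tuple[tuple[int, int], str]] = []
    for start in range(lo, hi - window + 2):
        span = (start, start + window - 1)
        reason = None
        burial, rel, cons, divs, letters = [], [], [], [], []
        any_div_site = False
        for rn in range(span[0], span[1] + 1):
            es = exp_sites.get(rn)
            if es is None:
                reason = f"residue {rn} missing from exposure profile"
                break
            if es.rel_exposure_open is None:
                reason = f"residue {rn} ({es.resname}) has no reference exposure area"
                break
            cs = conservation.sites.get(rn)
            if cs is None or cs.target_conservation is None:
                reason = f"residue {rn} undefined in conservation profile"
                break
            burial.append(
                0.0 if es.sasa_open <= 0 else min(1.0, max(0.0, es.delta_sasa / es.sasa_open))
            )
            rel.append(es.rel_exposure_open)
            cons.append(cs.target_conservation)
            if cs.offtarget_divergence is not None:
                any_div_site = True
                divs.append(cs.offtarget_divergence)
            letters.append(seq1(es.resname, undef_code="X"))
        if reason is not None:
            skipped.append((span, reason))
            continue
        n = len(burial)
        comp = [
            (sum(burial) / n, weights[0]),
            (sum(rel) / n, weights[1]),
            (sum(cons) / n, weights[2]),
        ]
        div_mean = sum(divs) / len(divs) if any_div_site else None
        if div_mean is not None:
            comp.append((div_mean, weights[3]))
        scored.append(
            dict(
                span=span,
                sequence="".join(letters),
                burial=comp[0][0],
                exposure=comp[1][0],
                conservation=comp[2][0],
                divergence=div_mean,
                composite=combine(comp),
            )
        )
    if not scored and not skipped:
        raise EpistateError("no windows could be scored")
    scored.sort(key=lambda d: (-d["composite"], d["span"][0]))
    candidates = [
        CandidateEpitope(
            span=d["span"],
            sequence=d["sequence"],
            burial_closed=d["burial"],
            exposure_open=d["exposure"],
            conservation=d["conservation"],
            divergence=d["divergence"],
            composite=d["composite"],
            rank=i + 1,
        )
        for i, d in enumerate(scored)
    ]
    return ScanResult(candidates=candidates, skipped=skipped, window=window, weights=weights)


def annotate_motif(candidate, motif: str) -> tuple[bool, int | None]:
    """Exact substring search of a motif (e.g. the ψRACK sequence) in a peptide.

    Accepts a :class:`CandidateEpitope` or a plain sequence string; returns
    ``(found, 1-based position or None)``.
    """
    if not motif:
        raise EpistateError("motif must be non-empty")
    seq = candidate.sequence if isinstance(candidate, CandidateEpitope) else str(candidate)
    pos = seq.find(motif)
    return (pos >= 0, pos + 1 if pos >= 0 else None)
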
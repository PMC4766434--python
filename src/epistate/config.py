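"""Plain-text run configuration for the pipeline CLI.

The config file is line-oriented ``key = value`` text; ``#`` starts a comment.
Recognized keys::

    structure        = path to the input PDB file
    domain.regulatory= A:152-292        # chain:start-end, author numbering
    domain.partner   = A:342-600
    linker           = 293-341          # inter-domain connector to delete
    alignment        = path to FASTA/Clustal alignment
    reference        = id of the alignment sequence mapped to the structure
    offset           = structure residue number of the reference's 1st residue
    family.<seqid>   = target | offtarget
    contact_cutoff   = 4.5
    salt_bridge_cutoff = 4.0
    probe            = 1.4
    sasa_points      = 960
    window           = 15
    weights          = 1,1,1,1          # burial, exposure, conservation, divergence
    motif            = SVEIWD           # optional, annotated on candidates
    pixel_cuts       = 100,175,220
    ihc_manifest     = CSV with columns sample_id,cohort,image[,mask]
    ihc_scores       = CSV with columns sample_id,cohort,score
    seed             = 0
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParseError
from .structure import DomainAnnotation

__all__ = ["RunConfig", "parse_config", "load_config"]


@dataclass
class RunConfig:
    structure: Path | None = None
    domains: dict[str, DomainAnnotation] = field(default_factory=dict)
    linker: tuple[int, int] | None = None
    alignment: Path | None = None
    reference: str | None = None
    offset: int = 1
    families: dict[str, str] = field(default_factory=dict)
    contact_cutoff: float = 4.5
    salt_bridge_cutoff: float = 4.0
    probe: float = 1.4
    sasa_points: int = 960
    window: int = 15
    weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    motif: str | None = None
    pixel_cuts: tuple[int, int, int] = (100, 175, 220)
    ihc_manifest: Path | None = None
    ihc_scores: Path | None = None
    seed: int = 0

    def require(self, *names: str) -> None:
        for name in names:
            if getattr(self, name) in (None, {}):
                raise ParseError(f"config is missing required key {name!r}")

    def validate_paths(self) -> None:
        for name in ("structure", "alignment", "ihc_manifest", "ihc_scores"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ParseError(f"config {name} = {p}: file does not exist")
        for c in (self.contact_cutoff, self.salt_bridge_cutoff, self.probe):
            if c <= 0:
                raise ParseError("cutoffs and probe radius must be positive")


def _parse_span(value: str, key: str) -> tuple[int, int]:
    try:
        lo, hi = value.split("-")
        return int(lo), int(hi)
    except ValueError as exc:
        raise ParseError(f"config {key}: expected START-END, got {value!r}") from exc


def _parse_domain(value: str, key: str) -> DomainAnnotation:
    try:
        chain, span = value.split(":")
        lo, hi = _parse_span(span, key)
    except ValueError as exc:
        raise ParseError(f"config {key}: expected CHAIN:START-END, got {value!r}") from exc
    return DomainAnnotation(name=key.split(".", 1)[1], chain_id=chain.strip(), start=lo, end=hi)


def parse_config(text: str, base_dir: Path | None = None) -> RunConfig:
    cfg = RunConfig()
    base = Path(base_dir) if base_dir else Path(".")

    def path_of(v: str) -> Path:
        p = Path(v)
        return p if p.is_absolute() else base / p

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"config line {lineno}: expected key = value, got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        if key == "structure":
            cfg.structure = path_of(value)
        elif key.startswith("domain."):
            dom = _parse_domain(value, key)
            cfg.domains[dom.name] = dom
        elif key == "linker":
            cfg.linker = _parse_span(value, key)
        elif key == "alignment":
            cfg.alignment = path_of(value)
        elif key == "reference":
            cfg.reference = value
        elif key == "offset":
            cfg.offset = int(value)
        elif key.startswith("family."):
            fam = value.lower()
            if fam not in ("target", "offtarget"):
                raise ParseError(f"config line {lineno}: family must be target/offtarget")
            cfg.families[key.split(".", 1)[1]] = fam
        elif key == "contact_cutoff":
            cfg.contact_cutoff = float(value)
        elif key == "salt_bridge_cutoff":
            cfg.salt_bridge_cutoff = float(value)
        elif key == "probe":
            cfg.probe = float(value)
        elif key == "sasa_points":
            cfg.sasa_points = int(value)
        elif key == "window":
            cfg.window = int(value)
        elif key == "weights":
            parts = tuple(float(v) for v in value.split(","))
            if len(parts) != 4:
                raise ParseError(f"config line {lineno}: weights needs 4 values")
            cfg.weights = parts
        elif key == "motif":
            cfg.motif = value
        elif key == "pixel_cuts":
            parts = tuple(int(v) for v in value.split(","))
            if len(parts) != 3:
                raise ParseError(f"config line {lineno}: pixel_cuts needs 3 values")
            cfg.pixel_cuts = parts
        elif key == "ihc_manifest":
            cfg.ihc_manifest = path_of(value)
        elif key == "ihc_scores":
            cfg.ihc_scores = path_of(value)
        elif key == "seed":
            cfg.seed = int(value)
        else:
            raise ParseError(f"config line {lineno}: unknown key {key!r}")
    return cfg


def load_config(path) -> RunConfig:
    p = Path(path)
    cfg = parse_config(p.read_text(), base_dir=p.parent)
    cfg.validate_paths()
    return cfg
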
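class EpistateError(Exception):
    """Base class for all errors raised by epistate."""


class ParseError(EpistateError):
    """Malformed input file (PDB, alignment, config, manifest)."""


class GeometryError(EpistateError):
    """A geometric precondition is violated (undefined cell, empty domain, ...)."""
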
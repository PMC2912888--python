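"""Exception hierarchy."""


class TetrapotError(Exception):
    """Base class for package errors."""


class ParseError(TetrapotError):
    """Unreadable or malformed input file."""


class EmptyStructureError(TetrapotError):
    """A structure with no residues where one is required."""


class FormatError(TetrapotError):
    """Malformed tabular input (rotamer library, config tables)."""


class ParameterError(TetrapotError):
    """Out-of-range parameter value."""


class BuildError(TetrapotError):
    """Side-chain construction failure (missing backbone and the like)."""


class FitError(TetrapotError):
    """Calibration fit cannot be performed."""


class InfeasibleGeometryError(TetrapotError):
    """A requested distance quadruple cannot be embedded in 3-space."""
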
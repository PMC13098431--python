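"""Exception hierarchy shared across the package."""


class SdrCensusError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SdrCensusError):
    """A structure or trajectory file could not be parsed."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class EmptyInputError(SdrCensusError):
    """An operation received no usable data (zero atoms, empty samples...)."""


class TruncationError(ParseError):
    """A trajectory file ended in the middle of a frame."""


class TopologyMismatchError(SdrCensusError):
    """Frame atom count does not match the topology."""


class EmptySelectionError(SdrCensusError):
    """A selection resolved to no atoms."""


class DegenerateGeometryError(SdrCensusError):
    """Zero-length arm, collinear dihedral frame, or similar degeneracy."""


class PlanarRingError(SdrCensusError):
    """Puckering amplitude below the planarity threshold; phi/theta undefined."""


class ConfigurationError(SdrCensusError):
    """A criteria/config mapping is incomplete or inconsistent."""


class UndefinedFractionError(SdrCensusError):
    """A census was requested over an empty denominator."""


class InfeasibleGeometryError(SdrCensusError):
    """The synthetic generator cannot realize the requested geometry."""
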
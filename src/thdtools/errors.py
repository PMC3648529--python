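"""Exception hierarchy shared across the toolkit."""


class ThdToolsError(Exception):
    """Base class for all toolkit errors."""


class ParseError(ThdToolsError):
    """A coordinate file or symmetry triplet could not be parsed."""


class EmptyStructureError(ThdToolsError):
    """A file contained no atoms."""


class FormatCapacityError(ThdToolsError):
    """The requested output format cannot represent the structure (e.g. >62 chains in PDB)."""


class GeometryError(ThdToolsError):
    """Degenerate geometry: rank-deficient point sets, zero-volume cells, too few atoms."""


class MetadataError(ThdToolsError):
    """Required metadata (crystal cell, operators) is missing."""


class SymmetryDetectionError(ThdToolsError):
    """Chains expected to be symmetry-equivalent are not superposable."""


class ConfigurationError(ThdToolsError):
    """Missing per-atom configuration, e.g. vdW radii not assigned before SASA."""


class InputError(ThdToolsError):
    """Invalid combination of arguments (overlapping groups, non-polymer chain, ...)."""


class DockingError(ThdToolsError):
    """No template could be aligned to the query assembly."""


class MinimizationError(ThdToolsError):
    """Rigid-body minimization diverged; carries the energy trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace or []


class DomainError(ThdToolsError):
    """Argument outside the mathematical domain of a formula (e.g. kd <= 0)."""
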
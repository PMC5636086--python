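"""Exception hierarchy.

Every error raised by this package derives from :class:`NgeniError`, so
callers (including the CLI) can distinguish data problems from numerical
failures with two ``except`` clauses.
"""


class NgeniError(Exception):
    """Base class for all package errors."""


class FormatError(NgeniError):
    """Input file could not be parsed."""


class EmptySelectionError(NgeniError):
    """A structure selection produced zero C-alpha atoms."""


class PairingError(NgeniError):
    """Two structures share too few residues to form a pair."""


class DimensionError(NgeniError):
    """Array shapes are incompatible."""


class ParameterError(NgeniError):
    """A user-supplied parameter is out of range."""


class ConnectivityError(NgeniError):
    """The elastic network is not a connected graph."""


class GeometryError(NgeniError):
    """Degenerate geometry (coincident beads, near-zero vectors)."""


class SolverError(NgeniError):
    """An eigensolver or linear solver failed."""


class StepFailureError(NgeniError):
    """A pathway step could not reduce the cost even after safeguarding."""


class ComparisonError(NgeniError):
    """Two pathways are incompatible for metric comparison."""
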
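"""Exception types shared across the toolkit."""


class PlacefragError(Exception):
    """Base class for all toolkit errors."""


class AlignmentShapeError(PlacefragError):
    """Alignment records do not share a common column count."""


class IdentifierError(PlacefragError):
    """Duplicate, unknown, or unresolvable sequence/tip identifiers."""


class WindowRangeError(PlacefragError):
    """A column window falls outside the alignment bounds."""


class CoverageError(PlacefragError):
    """Tree tips are not covered by the reference alignment."""


class EdgeReferenceError(PlacefragError):
    """A placement references an edge (or position on it) that does not exist."""


class InsufficientOverlapError(PlacefragError):
    """Too few shared tips between two trees for a comparison."""


class UndefinedCorrelationError(PlacefragError):
    """A correlation is undefined (zero variance in one distance vector)."""


class SaturationError(PlacefragError):
    """A resampling retry budget was exhausted (e.g. mutant space saturated)."""


class InvariantViolationError(PlacefragError):
    """A domain-type invariant was violated (e.g. a fragment with no origins)."""
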
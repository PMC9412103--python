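"""Exception hierarchy shared by all modules.

Every error raised by the package derives from :class:`BionicVeinError`,
so callers (and the CLI) can distinguish domain failures (exit 1) from
usage mistakes (exit 2).
"""


class BionicVeinError(Exception):
    """Base class for all package errors."""


class DomainError(BionicVeinError, ValueError):
    """A numeric argument lies outside its mathematical domain."""


class StructureError(BionicVeinError):
    """A vein graph or adjacency pair violates its structural invariants."""


class ValidationError(BionicVeinError):
    """Semantic-parameter constraints are violated."""

    def __init__(self, message, violations=None):
        super().__init__(message)
        self.violations = list(violations or [])


class GeometryError(BionicVeinError):
    """Sketch / mesh construction failed (degenerate or self-intersecting)."""


class FormatError(BionicVeinError):
    """A file could not be parsed in the expected format."""


class VersionError(FormatError):
    """A database file declares an unsupported schema version."""


class UsageError(BionicVeinError):
    """An API was called with an unsupported combination of arguments."""
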
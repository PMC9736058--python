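"""Exception hierarchy.

Every error raised by the library derives from :class:`PkaDirectError`, so
callers (and the CLI) can map failure classes onto exit codes without
string-matching messages.
"""


class PkaDirectError(Exception):
    """Base class for all pkadirect errors."""


class InvalidValueError(PkaDirectError, ValueError):
    """A numeric input is non-finite or outside its physical domain."""


class InvalidConstantsError(PkaDirectError, ValueError):
    """Thermodynamic constants violate their invariants (e.g. T <= 0)."""


class SchemaError(PkaDirectError, ValueError):
    """A table or config file does not match the documented schema."""


class StoichiometryError(PkaDirectError, ValueError):
    """Species in a dissociation system disagree on explicit-water count."""


class AssemblyError(PkaDirectError, ValueError):
    """A four-species system could not be assembled (missing/duplicate role)."""


class ParseError(PkaDirectError, ValueError):
    """A QC output stream could not be parsed."""


class ConfigError(PkaDirectError, ValueError):
    """An unregistered functional/basis/solvation label or bad run config."""


class ProtocolViolationError(PkaDirectError, ValueError):
    """A protocol rule was violated (e.g. imaginary frequency on a minimum)."""


class TaggingError(PkaDirectError, ValueError):
    """Phenolic O/H atoms could not be identified in a geometry."""


class PlacementError(PkaDirectError, ValueError):
    """Explicit-water placement produced an unresolvable steric clash."""


class ClassificationError(PkaDirectError, ValueError):
    """Cage classification requested on a geometry without enough waters."""


class StatisticsError(PkaDirectError, ValueError):
    """A benchmark statistic was requested on degenerate input."""


class CoverageError(PkaDirectError, ValueError):
    """A benchmark record lacks the requested method column."""


class FitError(PkaDirectError, RuntimeError):
    """Nonlinear titration fit failed to converge."""


class DegenerateCurveError(PkaDirectError, ValueError):
    """Titration data carry no transition (flat within noise)."""
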
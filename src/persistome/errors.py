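"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`PersistomeError` so the CLI can
map any failure to a nonzero exit code with the stage name attached.
"""


class PersistomeError(Exception):
    """Base class for all package errors."""


class DesignError(PersistomeError):
    """Invalid or incomplete experimental design (missing arm, <2 lines...)."""


class TruthConfigError(PersistomeError):
    """Inconsistent planted-truth configuration (zero effect, fold < 1...)."""


class CapacityError(PersistomeError):
    """A planting request exceeds what the manifest can host."""


class FilterError(PersistomeError):
    """Feature filtering removed everything, or a report is inconsistent."""


class AnnotationError(PersistomeError):
    """A feature is missing from the manifest it is supposed to derive from."""


class StatsError(PersistomeError):
    """Degenerate statistical input (singular design, zero variances...)."""


class ParseError(PersistomeError):
    """Malformed input file; carries the offending line number when known."""
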
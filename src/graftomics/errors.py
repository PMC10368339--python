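"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`GraftomicsError`, so callers can catch one type at pipeline
boundaries while still seeing builtin-compatible semantics
(``ConfigError`` is a ``ValueError``, etc.).
"""


class GraftomicsError(Exception):
    """Base class for all package errors."""


class ConfigError(GraftomicsError, ValueError):
    """Invalid simulation or run configuration."""


class InputError(GraftomicsError, ValueError):
    """Invalid data passed to an operation (empty group, negative value...)."""


class CoordinateError(GraftomicsError, ValueError):
    """A genomic coordinate falls outside the reference."""


class SiteTypeError(InputError):
    """An operation restricted to cytosine sites was given a non-cytosine site."""


class DegenerateNullError(GraftomicsError, ValueError):
    """The empirical null distribution has zero spread and cannot be fitted."""


class ScoringError(GraftomicsError, ValueError):
    """Calls and truth tables cannot be joined (orphan keys)."""


class PipelineError(GraftomicsError, RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""
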
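"""Exception hierarchy shared across the pipeline.

Every stage raises one of these instead of a bare ValueError/KeyError so that
callers (and the CLI) can distinguish bad arguments from structural problems
in a generated or supplied design.
"""


class RepspaceError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(RepspaceError, ValueError):
    """An argument violates a documented precondition."""


class DesignError(RepspaceError, ValueError):
    """A trial design is structurally unusable (e.g. disconnected pairing graph)."""


class EmptyDesignError(DesignError):
    """No trials rate the requested dimension; nothing to solve."""


class MissingImageError(RepspaceError, KeyError):
    """An image (or concept) is absent from a space or similarity structure."""


class UndefinedCorrelationError(RepspaceError, ValueError):
    """A correlation is undefined because one input vector is constant."""


class InsufficientDataError(RepspaceError, ValueError):
    """Too few observations or classes to compute the requested statistic."""


class UnknownRecipeError(RepspaceError, KeyError):
    """Requested analysis recipe is not registered."""
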
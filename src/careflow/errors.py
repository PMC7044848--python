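"""Exception hierarchy for the careflow package.

Every error raised deliberately by the library derives from
:class:`CareflowError`, so pipeline orchestration can catch one type and
report the failing stage without masking programming errors.
"""


class CareflowError(Exception):
    """Base class for all careflow-specific errors."""


class InvalidParameterError(CareflowError, ValueError):
    """A caller-supplied parameter is out of its documented range."""


class FormatError(CareflowError, ValueError):
    """An input file violates the documented dialect."""


class ValidationError(CareflowError, ValueError):
    """A domain object violates its invariants (e.g. a non-stochastic
    routing matrix or an unreachable discharge state)."""


class SimulationError(CareflowError, RuntimeError):
    """Patient-movement simulation failed (e.g. the per-admission event
    cap was hit, indicating near-non-absorbing routing)."""


class DegenerateDataError(CareflowError, ValueError):
    """Data carry no information for the requested fit (e.g. a
    zero-variance power-law tail)."""


class InsufficientDataError(CareflowError, ValueError):
    """Too few observations to perform the requested fit."""


class DegenerateReferenceError(CareflowError, RuntimeError):
    """A null-model reference network could not be constructed (graph too
    small, too dense, or impossible to rewire)."""
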
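"""Exception hierarchy shared across the pipeline stages."""


class SipScopeError(Exception):
    """Base class for all package-specific errors."""


class DomainError(SipScopeError, ValueError):
    """A physical quantity lies outside its valid domain."""


class FormatError(SipScopeError, ValueError):
    """An input table or sequence file violates the expected format."""


class EstimationError(SipScopeError, ValueError):
    """A quantity cannot be estimated from the supplied data."""


class IncomparabilityError(SipScopeError, ValueError):
    """Two gradient profiles cannot be compared (e.g. disjoint density ranges)."""


class DegenerateProfileError(SipScopeError, ValueError):
    """A skew profile is flat or otherwise carries no replication signal."""


class CoordinateError(SipScopeError, ValueError):
    """A sequence coordinate is outside the genome bounds."""


class PipelineError(SipScopeError, RuntimeError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
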
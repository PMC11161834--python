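"""Exception types shared across the pipeline."""


class CircsatError(Exception):
    """Base class for all package errors."""


class ValidationError(CircsatError):
    """A domain object violates its invariants."""


class ParameterError(CircsatError):
    """A user-supplied parameter is out of range."""


class GenerationError(CircsatError):
    """The simulator could not realize a requested structure."""
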
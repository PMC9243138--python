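"""Exception hierarchy shared across the package."""


class NoxtactError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NoxtactError):
    """A domain object violates one of its invariants."""


class FormatError(NoxtactError):
    """An input file does not conform to the documented layout."""


class ParameterError(NoxtactError):
    """An operation was called with out-of-range or inconsistent parameters."""


class StimulusError(NoxtactError):
    """A stimulus window could not be located in a trace."""


class DegenerateInputError(NoxtactError):
    """Input is formally valid but the requested quantity is undefined on it
    (e.g. zero variance, all-tied differences, constant image)."""
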
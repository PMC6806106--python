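"""Exception hierarchy shared across the package."""


class HamadlError(Exception):
    """Base class for all package errors."""


class FormatError(HamadlError):
    """A file does not conform to the documented column layout."""


class DataError(HamadlError):
    """Input values violate an invariant (duplicate frames, bad intervals, ...)."""


class ParameterError(HamadlError):
    """A parameter is inconsistent with the data (e.g. more clusters than points)."""
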
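"""Exception hierarchy shared across the package."""


class FdmortError(Exception):
    """Base class for all package errors."""


class ValidationError(FdmortError, ValueError):
    """Input violates a documented invariant (shape, sign, ordering, ...)."""


class ParseError(FdmortError, ValueError):
    """A file could not be parsed into a valid container."""


class FitError(FdmortError, RuntimeError):
    """A model could not be estimated or a forecaster failed."""
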
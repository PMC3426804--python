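"""Exception types shared across the package."""


class FdrsimError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FdrsimError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidInputError(FdrsimError, ValueError):
    """Input data violate a precondition (shape, labels, lengths)."""


class DegenerateInputError(FdrsimError, ValueError):
    """Input is formally valid but degenerate (e.g. all p-values identical)."""


class EstimationError(FdrsimError, RuntimeError):
    """An estimator could not produce a result (e.g. nonnegative curvature)."""


class ParseError(FdrsimError, ValueError):
    """A delimited file is malformed; the message carries the location."""
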
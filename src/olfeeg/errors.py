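"""Exception hierarchy shared across the package."""


class OlfeegError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(OlfeegError, ValueError):
    """An analysis parameter is outside its valid range."""


class ConfigurationError(OlfeegError, ValueError):
    """A configuration object is inconsistent; the message names the field."""


class DataError(OlfeegError, ValueError):
    """Input data violate a precondition (NaN, wrong dtype, ...)."""


class LevelError(ParameterError):
    """Requested decomposition depth exceeds what the signal length allows."""


class StructuralError(OlfeegError, ValueError):
    """Shapes or metadata of related objects do not line up."""


class StateError(OlfeegError, RuntimeError):
    """An estimator was used before being fitted."""


class DegenerateDataError(DataError):
    """Data are rank-deficient or constant where variability is required."""


class ConvergenceError(OlfeegError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""


class ProtocolError(OlfeegError, ValueError):
    """An evaluation protocol precondition is violated."""


class DivergenceError(OlfeegError, RuntimeError):
    """Training produced a non-finite loss; the message names the epoch."""
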
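"""Exception types shared across the package."""


class SDRSimError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(SDRSimError, ValueError):
    """A physical or numerical parameter is out of its valid range."""


class ShapeError(SDRSimError, ValueError):
    """Array or stack dimensions do not match the expected layout."""


class MetadataError(SDRSimError, ValueError):
    """A metadata sidecar is missing fields or fails schema validation."""


class PackingError(SDRSimError, RuntimeError):
    """Random placement could not satisfy the separation constraint."""


class SingularMatrixError(SDRSimError, ValueError):
    """The phase-unmixing system is rank deficient (m=0 or repeated phases)."""


class SingularModulationError(SingularMatrixError):
    """Modulation depth m = 0: coefficients are undefined."""


class UnsupportedConfigurationError(SDRSimError, ValueError):
    """A configuration outside the three-phase analytic solution."""


class FitFailureError(SDRSimError, RuntimeError):
    """A least-squares profile fit did not converge."""


class UndefinedCorrelationError(SDRSimError, ValueError):
    """Correlation requested on a constant image."""


class FrequencyRangeError(SDRSimError, ValueError):
    """A carrier frequency falls outside the padded spectral support."""
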
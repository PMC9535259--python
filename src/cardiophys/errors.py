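"""Exception hierarchy used across the package."""


class CardiophysError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(CardiophysError, ValueError):
    """Invalid parameters or malformed in-memory data."""


class FormatError(CardiophysError, ValueError):
    """A file does not conform to the documented on-disk format."""


class CapabilityError(CardiophysError, RuntimeError):
    """An optional backend (e.g. an ABF reader) is not available."""


class AnalysisError(CardiophysError, RuntimeError):
    """An analysis precondition failed on otherwise valid input."""


class FiducialError(AnalysisError):
    """A fiducial point could not be located within one ECG complex / AP."""


class PairingError(AnalysisError):
    """Paired records (pre/post, or matched animals) could not be aligned."""
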
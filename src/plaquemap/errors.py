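"""Exception hierarchy shared across the pipeline."""


class PlaquemapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PlaquemapError):
    """Invalid specification: unknown labels, out-of-grid regions, bad fields."""


class DomainError(PlaquemapError, ValueError):
    """Physically meaningless scalar input (non-positive T1, TR, ...)."""


class ProtocolError(PlaquemapError):
    """Acquisition protocol incompatible with the requested operation."""


class SamplingError(PlaquemapError):
    """ROI sampling could not satisfy the request; message names the class."""


class InputError(PlaquemapError, ValueError):
    """Malformed runtime input (out-of-grid voxel, dimension mismatch, empty table)."""
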
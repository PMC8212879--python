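"""Exception hierarchy shared across the package."""


class SHGMetricsError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SHGMetricsError):
    """On-disk stack or sidecar does not follow the documented layout."""


class StackValidationError(SHGMetricsError, ValueError):
    """In-memory stack violates a type invariant (negative intensity, shape mismatch...)."""


class ParameterError(SHGMetricsError, ValueError):
    """A physical/model parameter is outside its admissible range."""


class GeometryError(SHGMetricsError, ValueError):
    """Acquisition geometry is insufficient or inconsistent (too few angles, angle lists differ...)."""


class AngleLookupError(SHGMetricsError, KeyError):
    """Requested excitation angle is absent from a measured curve."""


class DepthRangeError(SHGMetricsError, ValueError):
    """Requested depth lies outside the sampled z-range."""


class PlacementError(SHGMetricsError, RuntimeError):
    """A synthetic fiber could not be placed inside the image bounds."""
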
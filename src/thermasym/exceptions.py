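"""Exception and warning hierarchy for the thermogram-analysis pipeline."""


class ThermasymError(Exception):
    """Base class for all package errors."""


class ThermogramFormatError(ThermasymError):
    """Raised when a temperature-matrix file cannot be parsed (e.g. ragged rows)."""


class ThermogramValidationError(ThermasymError):
    """Raised when a temperature matrix violates a physical-plausibility invariant."""


class ConfigError(ThermasymError):
    """Raised when a pipeline configuration value is out of its allowed range."""


class PhantomSpecError(ThermasymError):
    """Raised when a phantom specification is geometrically inconsistent."""


class NoEdgesError(ThermasymError):
    """Raised when an image has zero gradient everywhere (no edges can exist)."""


class DegenerateGeometryError(ThermasymError):
    """Raised for degenerate point sets: too few points, all collinear, etc."""


class EllipseFitError(ThermasymError):
    """Raised when the least-squares conic through the points is not an ellipse."""


class DegenerateSplitError(ThermasymError):
    """Raised when a symmetry-axis split leaves one side empty or the axis
    misses the analysis region entirely."""


class ProtocolError(ThermasymError):
    """Raised when a classification protocol precondition fails
    (missing class, too few members per class, empty manifest, ...)."""


class UndefinedMetricError(ThermasymError):
    """Raised when a confusion-matrix metric has a zero denominator."""


class AmbiguousAxisWarning(UserWarning):
    """Emitted when the fitted ellipse is nearly circular, so its major-axis
    direction (and hence the symmetry axis) is poorly determined."""
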
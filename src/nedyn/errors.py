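"""Exception hierarchy shared by all stages."""


class NedynError(Exception):
    """Base class for all package errors."""


class InputError(NedynError):
    """Bad or missing input data (files, arrays, argument combinations)."""


class FormatError(InputError):
    """A file parsed but violated the expected schema."""


class ConfigurationError(NedynError):
    """Missing calibration or inconsistent analysis configuration."""


class ParameterError(NedynError):
    """Synthetic-generator or analysis parameters outside their valid domain."""


class SegmentationError(NedynError):
    """Thresholding produced no usable object."""


class ContrastError(NedynError):
    """Degenerate intensity contrast (e.g. cytoplasm mean <= camera background)."""


class TraceError(NedynError):
    """Too many per-frame failures to build a usable time trace."""


class FitError(NedynError):
    """Nonlinear fit failed to converge after multistart."""


class GeometryError(NedynError):
    """Invalid polygon/polyline geometry."""


class NormalizationError(NedynError):
    """Normalization undefined (non-positive denominator or constant signal)."""


class SummaryError(NedynError):
    """No converged fits (or otherwise empty set) to summarize."""
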
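"""Exception hierarchy for the bmdyn pipeline."""


class BmdynError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(BmdynError, ValueError):
    """A geometry/profile/config parameter is out of its valid range."""


class RangeError(BmdynError, ValueError):
    """An arc coordinate or interval lies outside the follicle domain."""


class StepSizeError(BmdynError, ValueError):
    """Requested integration step exceeds the stability limit."""


class TraceError(BmdynError, RuntimeError):
    """Centerline ridge tracing failed (no ridge at the seed point)."""


class ProtocolError(BmdynError, RuntimeError):
    """An analysis assumption about the imaging protocol is violated."""


class FitError(BmdynError, RuntimeError):
    """Too few points (or degenerate data) for a regression fit."""


class EdgeLostError(BmdynError, RuntimeError):
    """Bleached-edge contrast too low to localize a fiducial."""


class EdgeCountError(BmdynError, RuntimeError):
    """Detected edge count does not match the expected count."""


class TieError(BmdynError, RuntimeError):
    """Ambiguous frame-to-frame edge matching (multiple candidates)."""


class GapError(BmdynError, RuntimeError):
    """A required frame/timepoint is missing from a track."""


class MeasureError(BmdynError, RuntimeError):
    """A morphometric measurement is undefined on this input."""


class ProximityError(BmdynError, ValueError):
    """An event lies too far from the BM trace to be referenced to it."""


class SeriesParseError(BmdynError, RuntimeError):
    """An image-series file could not be parsed."""


class ConfigError(BmdynError, ValueError):
    """A scenario/configuration file is inconsistent."""
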
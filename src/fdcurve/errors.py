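"""Exception types shared across the pipeline."""


class FDCurveError(Exception):
    """Base class for all fdcurve errors."""


class CurveParseError(FDCurveError):
    """A curve file could not be parsed; the message names the offending line."""


class DegenerateCurveError(FDCurveError):
    """A curve is too short or has zero extent on an axis."""


class ConfigError(FDCurveError):
    """An invalid parameter combination."""


class EncodingError(FDCurveError):
    """Derivative encoding failed (e.g. over-aggressive pruning threshold)."""


class FitError(FDCurveError):
    """A Worm-Like Chain fit failed; carries diagnostics in the message."""
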
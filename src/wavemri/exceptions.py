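"""Exception hierarchy for the pipeline."""


class WavemriError(Exception):
    """Base class for package-specific errors."""


class DimensionError(WavemriError, ValueError):
    """An image dimension is incompatible with the requested operation."""


class ConfigurationError(WavemriError, ValueError):
    """A network or run configuration is internally inconsistent."""


class DataError(WavemriError, ValueError):
    """A dataset violates a precondition (empty, single-class, ...)."""


class TrainingDivergenceError(WavemriError, RuntimeError):
    """Training produced a non-finite loss."""


class UndefinedMetricError(WavemriError, ZeroDivisionError):
    """A metric's denominator is zero for the given confusion counts."""
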
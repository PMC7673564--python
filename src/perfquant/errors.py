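"""Exception types shared across the package."""


class PerfquantError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PerfquantError, ValueError):
    """An argument violates a documented precondition."""


class UnsupportedFormatError(PerfquantError, ValueError):
    """Input file exists but is not in a supported format (e.g. RGB TIFF)."""


class ConfigurationError(PerfquantError, ValueError):
    """A configuration object or file is inconsistent or incomplete."""


class UnusableCurveError(PerfquantError, ValueError):
    """A time-intensity curve cannot be analyzed at all (e.g. no
    pre-injection frames for the baseline)."""


class CurveParseError(PerfquantError, ValueError):
    """A curve CSV file is malformed; message carries the row number."""


class TransformError(PerfquantError, ValueError):
    """A value cannot be transformed (zero/negative under reciprocal)."""


class UndefinedFlowError(PerfquantError, ValueError):
    """Microsphere flow is undefined (zero reference signal)."""
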
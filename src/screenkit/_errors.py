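"""Exception hierarchy shared across screenkit modules."""


class ScreenKitError(Exception):
    """Base class for all screenkit errors."""


class DataError(ScreenKitError):
    """Malformed, missing, or out-of-domain input data."""


class DegeneratePlateError(ScreenKitError):
    """Plate controls cannot anchor the inhibition scale (e.g. equal means)."""


class FitError(ScreenKitError):
    """A curve fit could not be set up (insufficient or invalid data)."""


class IC50UndefinedError(ScreenKitError):
    """Relative IC50 requested from a fit without a sigmoid midpoint."""
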
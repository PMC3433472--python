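"""Exception hierarchy shared across selexkit modules."""


class SelexkitError(Exception):
    """Base class for all selexkit errors."""


class ConfigurationError(SelexkitError):
    """Invalid configuration (duplicate barcodes, bad thresholds, missing files)."""


class InputError(SelexkitError):
    """Malformed input value (non-ACGT base, empty sequence, ...)."""


class ParseError(SelexkitError):
    """A file or report could not be parsed; message names the offending field."""


class FitError(SelexkitError):
    """A curve fit failed to converge or was degenerate."""


class EmptyPoolError(SelexkitError):
    """An operation requiring a non-empty round pool received an empty one."""
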
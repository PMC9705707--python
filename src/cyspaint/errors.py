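"""Exception hierarchy shared across the pipeline.

Command-line entry points map :class:`FormatError` to exit code 2 and
:class:`ConfigurationError` to exit code 3.
"""


class CysPaintError(Exception):
    """Base class for all package errors."""


class FormatError(CysPaintError):
    """An input file violates the expected format (missing column, bad value)."""


class ConfigurationError(CysPaintError):
    """A parameter or parameter combination is invalid."""


class FittingError(CysPaintError):
    """A statistical fit is impossible on the provided data (degenerate input)."""


class EmptyMatrixError(CysPaintError):
    """No protein survives the cross-stimulus comparison filters."""
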
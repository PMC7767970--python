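"""Exception hierarchy shared across the package.

The CLI maps these onto distinct exit codes, so library code should raise
the most specific class that applies.
"""


class OscimapError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OscimapError):
    """Invalid or missing configuration (bad parameter, missing metadata)."""

    exit_code = 2


class DataFormatError(OscimapError):
    """Malformed input data (ragged TIFF pages, length mismatches, ...)."""

    exit_code = 3


class NumericalError(OscimapError):
    """A computation could not produce a meaningful result."""

    exit_code = 4
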
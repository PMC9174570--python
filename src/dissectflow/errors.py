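"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to 3.
"""


class DissectflowError(Exception):
    """Base class for all package errors."""


class ConfigError(DissectflowError):
    """Invalid configuration (schema violation, bad parameter file)."""


class DataError(DissectflowError):
    """Invalid or inconsistent input data."""


class FormatError(DataError):
    """File-format problem (grid mismatch, missing metadata); names the file."""


class ParameterError(DissectflowError):
    """Out-of-range numeric parameter."""


class SizingError(ParameterError):
    """Geometry unresolvable at the requested grid spacing."""


class LandmarkError(DataError):
    """Landmark outside the grid or too far from the structure it references."""
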
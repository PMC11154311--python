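"""Exception hierarchy.

``ConfigError`` covers invalid user-supplied parameters/configuration
(CLI exit code 2); ``DataError`` covers problems with input data or with
requests that the data cannot satisfy (CLI exit code 3).
"""


class RasStatesError(Exception):
    """Base class for all rasstates errors."""


class ConfigError(RasStatesError):
    """Invalid configuration, thresholds, or generator parameters."""


class DataError(RasStatesError):
    """Input data is malformed, inconsistent, or insufficient."""


class StructureFormatError(DataError):
    """A structure (PDB) file could not be parsed."""


class TrajectoryFormatError(DataError):
    """A coordinate trajectory could not be read or is inconsistent."""


class RoleResolutionError(DataError):
    """A semantic atom role could not be bound to an atom."""
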
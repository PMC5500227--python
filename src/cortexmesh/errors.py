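"""Exception hierarchy shared across the package."""


class CortexMeshError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CortexMeshError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidDataError(CortexMeshError, ValueError):
    """Input data violate a documented precondition (e.g. nonpositive MSD)."""


class SchemaError(CortexMeshError, ValueError):
    """A table is missing required columns or has a malformed header."""


class DataError(CortexMeshError, ValueError):
    """A table row-level problem: non-monotone times, duplicate frames, ..."""


class ConfigError(CortexMeshError, ValueError):
    """A study configuration block failed validation."""


class EmptyInputError(CortexMeshError, ValueError):
    """An operation received an empty ensemble/image/distribution."""
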
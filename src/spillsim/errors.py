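"""Exceptions shared across the pipeline stages."""


class SpillSimError(Exception):
    """Base class for all package-specific errors."""


class OutsideDomainError(SpillSimError):
    """A query point lies outside the supported spatial domain."""


class DegenerateGeometryError(SpillSimError):
    """Too few / collinear points for a two-dimensional convex hull."""


class MissingVariableError(SpillSimError):
    """A required variable is absent from a gridded input file."""


class UnitMismatchError(SpillSimError):
    """A gridded input declares units other than the ones this package uses."""


class ConfigError(SpillSimError):
    """Invalid or inconsistent run configuration."""
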
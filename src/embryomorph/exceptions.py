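"""Exception hierarchy shared across the package.

Exit-code mapping used by the command line interface:
``ConfigError`` -> 2, ``SchemaError``/``DesignError`` -> 3,
``NumericalError`` -> 4.
"""


class EmbryomorphError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(EmbryomorphError):
    """A configuration does not conform to the landmark scheme."""


class DesignError(EmbryomorphError):
    """A dataset violates the balanced specimen x observer x trial design."""


class ParameterError(EmbryomorphError):
    """Invalid simulation or analysis parameters."""


class DegenerateShapeError(EmbryomorphError):
    """A landmark configuration is degenerate (coincident/collinear points)."""


class ConfigError(EmbryomorphError):
    """Invalid pipeline run configuration."""


class NumericalError(EmbryomorphError):
    """A numerical procedure failed (non-convergence, undefined result)."""
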
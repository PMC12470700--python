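"""Exception hierarchy for the creambosso package."""


class CreamBossoError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(CreamBossoError, ValueError):
    """An input value or shape violates an operation's preconditions."""


class ParameterError(CreamBossoError, ValueError):
    """A filter or configuration parameter is out of its valid domain."""


class DegenerateInputError(CreamBossoError, ValueError):
    """The input is formally valid but degenerate (e.g. an all-zero image
    when the reference intensity is taken from the image maximum)."""


class UndefinedMetricError(CreamBossoError, ArithmeticError):
    """A metric is mathematically undefined for this input (e.g. contrast
    of an image with zero mean)."""


class InfeasibleError(CreamBossoError, ValueError):
    """A constrained selection has an empty admissible set."""


class SchemaError(CreamBossoError, ValueError):
    """A CSV table does not conform to its declared schema."""


class ChannelError(CreamBossoError, ValueError):
    """A multi-channel image was supplied where grayscale is required."""
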
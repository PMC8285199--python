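"""Exception hierarchy shared across the toolkit."""


class MriToolError(Exception):
    """Base class for all toolkit errors."""


class InputError(MriToolError, ValueError):
    """Invalid data passed to an operation (shape, range, emptiness)."""


class ParameterError(MriToolError, ValueError):
    """Invalid model or algorithm parameter."""


class ConfigurationError(MriToolError, ValueError):
    """Invalid or inconsistent run configuration."""


class DegenerateInputError(InputError):
    """Input is formally valid but degenerate for the operation
    (e.g. an all-zero image passed to a log transform)."""


class NumericalError(MriToolError, ArithmeticError):
    """A numerical routine failed to produce a finite, usable result."""


class FormatError(MriToolError, ValueError):
    """Unsupported or malformed file format."""
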
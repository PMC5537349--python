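"""Exception hierarchy used across the package."""


class CoextnetError(Exception):
    """Base class for all package-specific errors."""


class NetworkValidationError(CoextnetError, ValueError):
    """An interaction network violates a structural invariant."""


class FormatError(CoextnetError, ValueError):
    """An input file does not match the expected dialect."""


class DependenceError(CoextnetError, ValueError):
    """A dependence value is undefined or out of range."""


class CascadeError(CoextnetError, RuntimeError):
    """Illegal operation on a cascade state (e.g. removing an extinct species)."""


class ConvergenceError(CoextnetError, RuntimeError):
    """An iterative numerical routine failed to converge."""


class SizeError(CoextnetError, ValueError):
    """Problem size exceeds what an exact routine can enumerate."""


class ConfigError(CoextnetError, ValueError):
    """Invalid simulation or generator configuration."""
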
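"""Exception types shared across the package."""


class RibodenseError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(RibodenseError):
    """A simulation or analysis configuration is invalid or infeasible."""


class SchemaError(RibodenseError):
    """An input table does not conform to the expected columns / scheme."""
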
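"""Exception hierarchy shared across the package."""


class TelisimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TelisimError):
    """Invalid geometry, material, resolution or run configuration."""


class SolverError(TelisimError):
    """A numerical solve failed or produced unphysical output."""


class DataError(TelisimError):
    """Malformed trace data or inconsistent trace metadata."""
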
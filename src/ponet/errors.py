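"""Exception hierarchy shared across the package."""


class PonetError(Exception):
    """Base class for all package errors."""


class ConfigError(PonetError):
    """Invalid or infeasible configuration."""


class PairingError(PonetError):
    """Total/polysomal sample grids cannot be matched."""


class FormatError(PonetError):
    """Malformed on-disk input."""


class DegenerateInputError(PonetError):
    """Input is structurally valid but the requested statistic is undefined."""
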
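"""Exception types raised across the package."""


class PetasymError(ValueError):
    """Base class for all package-specific errors."""


class ConfigError(PetasymError):
    """Invalid simulation or pipeline configuration."""


class SizingError(ConfigError):
    """Grid too small to place the requested atlas regions."""


class AlignmentError(PetasymError):
    """Volume and atlas grids or affines do not match."""


class AtlasError(PetasymError):
    """Malformed atlas (empty labels, unknown labels, broken pairs)."""


class PairingError(PetasymError):
    """A region pair is missing one hemisphere."""


class ParseError(PetasymError):
    """Malformed serialized model or feature table."""
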
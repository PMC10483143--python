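"""Exception hierarchy shared across the package."""


class SoundArenaError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(SoundArenaError, ValueError):
    """A position falls outside the arena, or maps outside it after calibration."""


class ConfigurationError(SoundArenaError, ValueError):
    """A session configuration is missing a required field or is inconsistent."""


class SequencingError(SoundArenaError, ValueError):
    """Frames were fed to the closed-loop engine out of time order."""


class TruncationError(SoundArenaError, ValueError):
    """A trajectory is shorter than the phase schedule it is replayed against."""


class FormatError(SoundArenaError, ValueError):
    """A trajectory file does not match any accepted CSV dialect."""


class EmptyWindowError(SoundArenaError, ValueError):
    """No valid frames fall inside the requested analysis window."""


class PairingError(SoundArenaError, ValueError):
    """Phase results passed together do not form a habituation/exposure pair."""


class ParameterError(SoundArenaError, ValueError):
    """A numeric parameter is outside its valid range."""


class DesignError(SoundArenaError, ValueError):
    """A statistical design is incomplete, unbalanced, or too small."""


class InputError(SoundArenaError, ValueError):
    """An input container is empty or otherwise unusable."""
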
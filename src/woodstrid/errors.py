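"""Exception hierarchy for the package."""


class WoodstridError(Exception):
    """Base class for all package errors."""


class AudioFormatError(WoodstridError):
    """WAV file exists but is not a supported mono PCM format."""


class MultiChannelError(AudioFormatError):
    """WAV file has more than one channel."""


class ManifestError(WoodstridError):
    """Recording manifest is malformed or fails validation."""


class SignalTooShortError(WoodstridError):
    """Signal shorter than one analysis window."""


class ScaleError(WoodstridError):
    """Operation received data on the wrong amplitude scale (linear vs dB)."""


class FitError(WoodstridError):
    """Model fitting failed or its preconditions were not met."""
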
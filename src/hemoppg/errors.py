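"""Exception hierarchy for hemoppg.

Every error raised deliberately by the package derives from :class:`HemoppgError`
so callers can catch the package's failures with a single except clause.
"""


class HemoppgError(Exception):
    """Base class for all hemoppg errors."""


class InvalidPairError(HemoppgError):
    """A wavelength-ratio was requested for a channel against itself."""


class InvalidSignalError(HemoppgError):
    """A signal violates a physical precondition (e.g. non-positive DC)."""


class TooShortError(HemoppgError):
    """The signal is too short for the requested operation."""


class NoPulseError(HemoppgError):
    """No cardiac spectral peak found above the noise floor in the search band."""


class DegenerateChannelError(HemoppgError):
    """A channel has zero pulsatile amplitude; ratios are undefined."""


class UnusableRecordError(HemoppgError):
    """A subject record yielded no valid analysis window on every channel."""


class DegenerateTargetError(HemoppgError):
    """The regression target is constant; feature ranking is undefined."""


class ConfigError(HemoppgError):
    """An experiment configuration contains an unknown or invalid key."""
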
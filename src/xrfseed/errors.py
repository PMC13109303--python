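"""Exception hierarchy for the xrfseed package."""


class XrfSeedError(Exception):
    """Base class for all xrfseed errors."""


class DimensionMismatchError(XrfSeedError):
    """Arrays that must share a pixel grid do not."""


class DegenerateInputError(XrfSeedError):
    """Input is constant / empty / single-class where variation is required."""


class PackingError(XrfSeedError):
    """Synthetic layout generation could not place all requested objects."""


class PolylineError(XrfSeedError):
    """A polyline file is malformed or out of the image grid."""


class ConfigError(XrfSeedError):
    """Pipeline configuration is invalid; message enumerates all violations."""
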
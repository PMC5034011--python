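"""Exception hierarchy for the plaquefuse pipeline."""


class PlaquefuseError(Exception):
    """Base class for all plaquefuse errors."""


class ConfigurationError(PlaquefuseError):
    """Invalid configuration value; the message names the offending field."""


class SegmentationError(PlaquefuseError):
    """No admissible contour path exists under the given constraints."""


class ReconstructionError(PlaquefuseError):
    """Biplane geometry cannot be reconstructed from the given projections."""


class RegistrationError(PlaquefuseError):
    """Landmark set cannot produce a valid (monotone) registration."""


class FusionError(PlaquefuseError):
    """Cap and WSS maps cannot be fused (e.g. grid mismatch)."""


class NormalizationError(PlaquefuseError):
    """WSS map cannot be normalized (zero or undefined median)."""


class FormatError(PlaquefuseError):
    """External file does not match the expected format."""
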
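"""Exception hierarchy shared across the pipeline."""


class PathscreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PathscreenError):
    """A simulation or pipeline configuration value is invalid.

    The message names the offending field.
    """


class InputError(PathscreenError):
    """Input data violates a documented precondition."""


class LayoutError(ConfigurationError):
    """Plate layout cannot accommodate the requested wells."""


class NormalizationError(PathscreenError):
    """A well could not be normalized (e.g. non-positive fitted value)."""


class SizeError(PathscreenError):
    """Problem size exceeds what an exact method can enumerate."""
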
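"""Exception hierarchy shared across the package."""


class MyoquantError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(MyoquantError, ValueError):
    """A parameter violates a documented invariant (non-positive dt, etc.)."""


class GenerationError(MyoquantError, RuntimeError):
    """A synthetic-data constraint could not be satisfied (e.g. overlap)."""


class DegenerateTrackError(MyoquantError, ValueError):
    """A bead track has (near-)zero variance and cannot calibrate a trap."""


class NoLinearRegionError(MyoquantError, RuntimeError):
    """No prefix of a force-extension curve satisfies the linearity criteria."""


class UndefinedIndexError(MyoquantError, ZeroDivisionError):
    """A morphometric index has a zero denominator (no MyHC+ nuclei/area)."""


class ConfigError(MyoquantError, ValueError):
    """A run configuration failed schema validation."""
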
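"""Exception types shared across the pipeline.

Every failure mode that the measurement or simulation contracts promise to
report explicitly gets its own class, so callers can distinguish e.g. a
degenerate statistical input from a configuration mistake.
"""


class PlacmorphError(Exception):
    """Base class for all package errors."""


class PackingError(PlacmorphError):
    """Requested villi cannot be placed without overlap within the retry budget."""


class CollinearStainsError(PlacmorphError):
    """Stain basis is rank-deficient (vectors collinear); deconvolution is ill-posed."""


class StainKindError(PlacmorphError):
    """Operation applied to an image of the wrong (or unknown) stain kind."""


class CalibrationMismatchError(PlacmorphError):
    """Inputs combined across stains do not share micron-per-pixel calibration."""


class DegenerateDataError(PlacmorphError):
    """Statistical input carries no information (e.g. all paired differences zero)."""


class UndefinedIndexError(PlacmorphError):
    """A morphometric index has a zero denominator (no villous area / no nuclei)."""


class SamplingFailureError(PlacmorphError):
    """Random field sampling exhausted its rejection budget without acceptance."""


class ConfigError(PlacmorphError):
    """Invalid configuration value; message names the offending key."""
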
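"""Exception hierarchy for mratlas."""


class MRAtlasError(Exception):
    """Base class for all mratlas errors."""


class FormatError(MRAtlasError):
    """A summary-statistics or LD file does not match the expected layout."""


class DuplicateVariantError(FormatError):
    """The same variant_id occurs more than once within one trait."""


class NoInstrumentsError(MRAtlasError):
    """Instrument selection left zero variants; the trait cannot be analyzed."""


class HarmonizationError(MRAtlasError):
    """Exposure and outcome panels could not be aligned (e.g. no shared variants)."""


class DispatchError(MRAtlasError):
    """An estimator was called with an instrument count outside its domain."""


class UndefinedRatioError(MRAtlasError):
    """A variant-exposure effect of exactly zero makes the ratio undefined."""


class CollinearityError(MRAtlasError):
    """The regression design is degenerate (all exposure effects identical)."""


class InsufficientInstrumentsError(MRAtlasError):
    """Too few instruments for the requested sensitivity analysis."""
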
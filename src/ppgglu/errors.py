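"""Exception hierarchy shared across the package.

Every error raised on a user-facing path derives from :class:`PPGError`, so
callers (and the command-line interface) can distinguish failures of this
package from programming errors.
"""


class PPGError(Exception):
    """Base class for all ppgglu errors."""


class ValidationError(PPGError, ValueError):
    """A parameter or domain object violates its invariants.

    The message names the offending field.
    """


class ParseError(PPGError, ValueError):
    """A waveform or table file could not be parsed."""


class MissingColumnError(ParseError):
    """A required CSV column is absent."""


class SegmentationError(PPGError, ValueError):
    """The waveform could not be segmented into beats."""


class DegenerateBeatError(PPGError, ValueError):
    """A beat is flat, monotone, or otherwise carries no usable morphology."""


class FeatureError(PPGError, ValueError):
    """A feature is undefined for the given beat (e.g. zero systolic time)."""
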
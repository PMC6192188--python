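"""Exception hierarchy.

All hapgeo errors derive from :class:`HapgeoError`; they also subclass
``ValueError`` so plain try/except ValueError works for callers that do
not care about the distinction.
"""


class HapgeoError(ValueError):
    """Base class for all hapgeo errors."""


class AlignmentError(HapgeoError):
    """The alignment itself is malformed (unequal lengths, empty, ...)."""


class InputError(HapgeoError):
    """Caller-supplied inputs are inconsistent (duplicate ids, bad format, ...)."""


class AnalysisError(HapgeoError):
    """The requested statistic is undefined for this input (n < 2, no columns, ...)."""
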
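"""Exception hierarchy for dualguide."""


class DualGuideError(Exception):
    """Base class for all dualguide errors."""


class ValidationError(DualGuideError, ValueError):
    """Input violates a documented contract (coordinates, alphabets, ids...)."""


class ParseError(DualGuideError, ValueError):
    """A file could not be parsed; message carries the offending line where known."""


class NoSequencesError(ParseError):
    """A genome file parsed cleanly but contained no sequences."""


class InsufficientFlankError(DualGuideError, ValueError):
    """Fewer than the required number of bases 5' of a PAM on its strand."""


class AmbiguousBaseError(DualGuideError, ValueError):
    """A spacer or PAM would contain an ambiguous (N) base."""


class SamplingExhaustedError(DualGuideError, RuntimeError):
    """Rejection sampling failed to find enough candidates within the attempt cap."""


class LayoutError(DualGuideError, ValueError):
    """Synthetic-genome layout is infeasible for the requested parameters."""


class WindowClippedWarning(UserWarning):
    """A target window was truncated at a contig end."""
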
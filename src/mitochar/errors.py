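"""Exception hierarchy."""


class MitocharError(Exception):
    """Base class for all package errors."""


class ParseError(MitocharError):
    """Input file cannot be parsed into an annotated genome."""


class CoordinateError(MitocharError):
    """Feature coordinates are inconsistent with the genome."""


class UndefinedCompositionError(MitocharError):
    """Composition or skew is undefined (empty/all-N sequence, zero denominator)."""


class FrameError(MitocharError):
    """Sequence length is incompatible with the required reading frame."""


class AlignmentRequiredError(MitocharError):
    """Blocks are ragged; concatenation requires pre-aligned input."""


class AbsentControlRegionError(MitocharError):
    """No AT-rich region annotation and no rrnS-trnM gap."""


class InfeasiblePlanError(MitocharError):
    """A generator plan violates a geometric or coding constraint."""
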
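"""Exception hierarchy for the pmaalink toolkit.

Every failure mode the pipeline can hit has a dedicated class so callers
(and the CLI) can report which stage failed and why; silent fallbacks
(e.g. a default response factor of 1.0) are deliberately absent.
"""


class PmaalinkError(Exception):
    """Base class for all pmaalink errors."""


class LinkageParseError(PmaalinkError):
    """A linkage shorthand string does not match the grammar."""


class DerivatizationError(PmaalinkError):
    """Invalid derivatization request (e.g. deuterating an anhydro sugar)."""


class UnsupportedDerivativeError(PmaalinkError):
    """Operation not defined for this derivative (e.g. fragments of anhydro PMAAs)."""


class MissingFactorError(PmaalinkError):
    """No response factor and no applicable increment rule for a PMAA label."""


class ChromatogramFormatError(PmaalinkError):
    """Malformed chromatogram file (non-numeric cells, non-monotone times...)."""


class IntegrationError(PmaalinkError):
    """Peak bounds outside the trace domain."""


class AmbiguousAssignmentError(PmaalinkError):
    """Two detected peaks fall within tolerance of a single library entry."""


class IndeterminateSplitError(PmaalinkError):
    """A shared peak cannot be split (e.g. both diagnostic EIC areas are zero)."""


class UnsupportedSplitError(PmaalinkError):
    """Shared-peak splitting is only defined for groups of exactly two members."""


class NormalizationError(PmaalinkError):
    """The anchor peak for chromatogram normalization was not found."""


class UndefinedRatioError(PmaalinkError):
    """Linkage ratio requested with a zero denominator."""
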
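"""Exception hierarchy for sigmatch.

All sigmatch errors derive from :class:`SigmatchError`, which itself derives
from ``ValueError`` so that callers using broad standard-library handling
still catch them.
"""


class SigmatchError(ValueError):
    """Base class for all sigmatch errors."""


class InvalidInputError(SigmatchError):
    """An argument violates a documented precondition."""


class FormatError(SigmatchError):
    """A file could not be parsed as the expected tabular format."""


class EmptySignatureError(SigmatchError):
    """A signature contains no usable (finite, named) entries after filtering."""


class NoOverlapError(SigmatchError):
    """Two signatures share no genes, so no comparison is possible."""


class ContractError(SigmatchError):
    """Two objects that must agree (e.g. on a shared gene universe) do not."""


class InsufficientDataError(SigmatchError):
    """Too few shared observations for the requested statistic."""


class EmptyRankingError(SigmatchError):
    """Every candidate model was skipped; no ranking can be produced."""
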
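"""Exception hierarchy shared across the package."""


class EpijsdError(Exception):
    """Base class for all package-specific errors."""


class DataFormatError(EpijsdError):
    """Malformed input data (pattern table, FASTA, SAM, BED)."""


class ParameterError(EpijsdError):
    """Invalid user-supplied parameter value."""


class UndefinedDistributionError(EpijsdError):
    """A pattern distribution was requested for a locus with zero depth."""


class DegenerateNullError(EpijsdError):
    """The empirical null cannot be fitted (zero spread in the scores)."""
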
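"""Exception hierarchy for the astruct pipeline.

Exit-code mapping used by the CLI: input problems (format, missing contig,
empty input) exit 2, an empty result set exits 3, anything else exits 1.
"""


class AstructError(Exception):
    """Base class for all astruct-specific errors."""


class InputFormatError(AstructError):
    """An input file could not be parsed in any supported format."""


class EmptyInputError(AstructError):
    """An input file parsed but contained zero usable records."""


class ContigMismatchError(AstructError):
    """A SNP contig is absent from the alignment file header."""


class EmptyResultError(AstructError):
    """The pipeline retained zero SNPs (nothing to report)."""


class InsufficientDataError(AstructError):
    """Too few informative bases/reads to compute a statistic."""


class EmptyProfileError(AstructError):
    """A reactivity profile has no non-missing values."""
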
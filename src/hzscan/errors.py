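"""Exception hierarchy for the hzscan pipeline."""


class HzscanError(Exception):
    """Base class for all pipeline errors."""


class AlignmentError(HzscanError):
    """Malformed multiple alignment (unequal lengths, duplicate ids, ...)."""


class AlphabetError(AlignmentError):
    """A sequence contains a character outside the allowed alphabet."""


class MetadataError(HzscanError):
    """Invalid sample or locus metadata."""


class EmptyInputError(HzscanError):
    """An input file or filtered collection is empty."""


class UndefinedStatisticError(HzscanError):
    """A statistic is undefined for this input (e.g. Tajima's D with S=0)."""


class MonomorphicSiteError(HzscanError):
    """A site is monomorphic where a polymorphic one is required."""


class NoTestError(HzscanError):
    """A hypothesis test cannot be carried out (constant vector, too few data)."""
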
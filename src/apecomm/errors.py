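"""Exception hierarchy shared across the package.

All apecomm-specific failures derive from :class:`ApecommError`, so callers
can catch one base class at the CLI boundary while library code raises the
most specific subclass.
"""


class ApecommError(Exception):
    """Base class for all apecomm errors."""


class RegistryError(ApecommError, KeyError):
    """A label is unknown to the active signal registry, or a parameter set
    does not cover the registry."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return Exception.__str__(self)


class DomainError(ApecommError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class DegeneratePosteriorError(ApecommError, ZeroDivisionError):
    """Both unnormalized intention weights are exactly zero, so the
    posterior cannot be normalized."""


class InfiniteLogitError(DomainError):
    """A cue weight of exactly 0 or 1 has an infinite log-odds."""


class ParseError(ApecommError, ValueError):
    """An input file does not conform to its declared schema."""


class InsufficientDataError(ApecommError, ValueError):
    """Too few matched combinations to compute a correlation."""


class UndefinedCorrelationError(ApecommError, ValueError):
    """A Pearson correlation is undefined because one of the two series is
    constant. This is a first-class reported outcome, not a NaN."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class IdentifiabilityError(ApecommError, ValueError):
    """The requested fit is not identifiable from the data given the
    supplied anchors."""
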
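"""Exception hierarchy shared across the package."""


class SpegkitError(Exception):
    """Base class for all spegkit errors."""


class ValidationError(SpegkitError, ValueError):
    """Malformed input (bad alphabet, inconsistent coordinates, bad config)."""


class RangeError(SpegkitError, ValueError):
    """A coordinate or length falls outside the usable sequence range."""


class OutOfFrameError(SpegkitError, ValueError):
    """A coordinate lies outside the annotated CDS / reading frame."""


class ConflictError(SpegkitError, ValueError):
    """A same-sense mutation collides with the intended edit."""


class InfeasibleSchemeError(SpegkitError, ValueError):
    """No synonymous substitution exists at a requested RTT position."""


class VariantUndefinedError(SpegkitError, ValueError):
    """The requested scaffold variant is undefined for the given hairpin."""


class DegenerateTestError(SpegkitError, ValueError):
    """All paired differences are zero; the signed-rank test is undefined."""


class UndefinedFoldError(SpegkitError, ZeroDivisionError):
    """Fold change over a zero control without a floor."""


class UsageError(SpegkitError, ValueError):
    """An operation was invoked on an incompatible experiment type."""


class DesignWarning(UserWarning):
    """Non-fatal designer condition (e.g. no feasible SSM scheme)."""
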
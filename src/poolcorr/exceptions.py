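"""Exception hierarchy shared across poolcorr modules."""


class PoolcorrError(Exception):
    """Base class for all poolcorr errors."""


class InvalidParameterError(PoolcorrError, ValueError):
    """Population or sample parameters violate a validity constraint
    (negative variance, Cauchy-Schwarz violation, bad weight, ...)."""


class UndefinedCorrelationError(PoolcorrError, ValueError):
    """A correlation limit or estimate is undefined (zero denominator).

    Raised instead of returning 0 or NaN: a silently propagated value
    would poison downstream summaries.
    """


class DataError(PoolcorrError, ValueError):
    """Malformed input data: bad TSV dialect, duplicate identifiers,
    annotation/matrix mismatch, non-numeric cells."""
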
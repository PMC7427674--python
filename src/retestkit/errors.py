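"""Exception hierarchy for retestkit.

Every data or configuration problem raises a subclass of
:class:`RetestKitError`, so callers (and the CLI) can catch one type.
"""


class RetestKitError(Exception):
    """Base class for all retestkit errors."""


class SchemaError(RetestKitError):
    """Input table is missing required columns or has an unusable layout."""


class ParseError(RetestKitError):
    """A cell could not be parsed (e.g. non-numeric measurement value)."""


class IncompletePairError(RetestKitError):
    """A (subject, region) has only one of the two sessions."""

    def __init__(self, offenders: list[tuple[str, str]]):
        self.offenders = offenders
        listing = "; ".join(f"subject {s!r} in region {r!r}" for s, r in offenders)
        super().__init__(f"incomplete test-retest pairs: {listing}")


class ValidationError(RetestKitError):
    """A domain invariant is violated (duplicate subjects, non-finite values, ...)."""


class InsufficientDataError(RetestKitError):
    """Fewer subjects than the operation requires (most need n >= 2)."""


class DegenerateVarianceError(RetestKitError):
    """All values identical: reliability statistics are undefined, not NaN."""


class UndefinedDenominatorError(RetestKitError):
    """A ratio statistic (COV, AbsVar) has a zero or negative denominator."""


class UnknownSubjectError(RetestKitError):
    """An exclusion names a subject that is not in the dataset."""


class SolverError(RetestKitError):
    """A numerical solver failed to converge."""
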
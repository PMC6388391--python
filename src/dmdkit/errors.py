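"""Exception hierarchy shared across the package."""


class DmdKitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DmdKitError, ValueError):
    """An input object violates a structural invariant."""


class HgvsParseError(DmdKitError, ValueError):
    """A coding-variant string does not match the supported grammar.

    Carries the offending token in ``token`` when one can be isolated.
    """

    def __init__(self, message: str, token: str | None = None):
        super().__init__(message)
        self.token = token


class CoordinateError(DmdKitError, ValueError):
    """A coding coordinate or exon index is outside the transcript."""


class ReferenceMismatchError(DmdKitError, ValueError):
    """The reference allele of a variant disagrees with the transcript CDS.

    Raised hard (never a warning): a mismatch means the wrong transcript
    model is in use and every downstream codon/CpG/PTC call would be wrong.
    """


class ContractError(DmdKitError, ValueError):
    """An operation was called outside its stated precondition."""


class UnsupportedSkipError(DmdKitError, ValueError):
    """A skip block includes the first or last coding exon (start/stop loss)."""
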
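"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`ConsentCodeError`, so callers (and the CLI) can catch one type.
"""

from __future__ import annotations


class ConsentCodeError(Exception):
    """Base class for all errors raised by consentcodes."""


class TokenSyntaxError(ConsentCodeError):
    """A consent-code token does not match the BASE(-PARAM)?((CC))? grammar."""

    def __init__(self, token: str, reason: str):
        self.token = token
        self.reason = reason
        super().__init__(f"malformed consent-code token {token!r}: {reason}")


class UnknownCodeError(ConsentCodeError):
    """A base code is not in the registry."""

    def __init__(self, code: str):
        self.code = code
        super().__init__(f"unknown consent code {code!r}")


class ParameterArityError(ConsentCodeError):
    """A parameter was given to a non-parameterized code, or omitted from a
    parameterized one."""

    def __init__(self, code: str, reason: str):
        self.code = code
        super().__init__(f"{code}: {reason}")


class CCNotAllowedError(ConsentCodeError):
    """The (CC) clinical-reference suffix was attached to a code that does not
    admit it (only GRU, HMB and DS do)."""

    def __init__(self, code: str):
        self.code = code
        super().__init__(
            f"{code}: the (CC) suffix is only allowed on GRU, HMB and DS"
        )


class ProfileValidationError(ConsentCodeError):
    """A consent profile failed validation; carries the full report."""

    def __init__(self, report):
        self.report = report
        msgs = "; ".join(
            f"[{v.rule_id}] {v.message}" for v in report.violations
            if v.severity == "error"
        )
        super().__init__(f"invalid consent profile: {msgs}")


class CrosswalkError(ConsentCodeError):
    """Malformed target identifier or unknown code in a crosswalk lookup."""


class CatalogError(ConsentCodeError):
    """Catalog file could not be read or an entry failed validation."""

    def __init__(self, message: str, dataset_id: str | None = None):
        self.dataset_id = dataset_id
        super().__init__(message)


class MatcherRequiredError(ConsentCodeError):
    """A parameterized code needed a term matcher but none was supplied."""
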
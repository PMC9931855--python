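"""Parsing consent-code tokens and validating consent profiles.

A *profile* is the set of consent codes attached to one shared resource
(a dataset or biospecimen collection): exactly one primary category, any
number of secondary modifiers, and requirement/permission codes. The token
grammar is ``BASE("-"PARAM)?("(CC)")?`` — e.g. ``HMB(CC)``, ``DS-CANCER(CC)``,
``TS-24``. The base is matched case-insensitively and canonicalized to
upper case; the parameter is free text, case-preserved but compared
case-insensitively after whitespace normalization.

Structural rules enforced here (each with a stable rule id):

========================  ==========================================================
SINGLE_PRIMARY            exactly one primary category ("pick only one")
NRES_COMPANIONS           an open-access (NRES) profile admits no other codes
HPOA_SCOPE                HPOA attaches only to HMB or DS profiles
GSO_SCOPE                 GSO attaches only to genetic resources
BIOSPECIMEN_SCOPE         GEN/CL attach only to biospecimen resources
SELF_CONTRADICTION        DS-X with NDS-X leaves an analytically empty permitted set
CC_RUO_REDUNDANT          (warning) RUO on a (CC) profile; RUO prevails
APPLICABILITY             (warning) code does not apply to the resource kind
UNKNOWN_CODE              (warning, permissive mode only) token carried opaquely
TS_PARAM_FORMAT           (warning) TS parameter is not an integer month count
MOR_PARAM_FORMAT          (warning) MOR parameter is not an ISO-8601 date
========================  ==========================================================
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import (
    CCNotAllowedError,
    ParameterArityError,
    ProfileValidationError,
    TokenSyntaxError,
    UnknownCodeError,
)
from .registry import CodeDefinition, Tier, get_registry
from .terms import normalize_term

__all__ = [
    "CodeInstance",
    "ConsentProfile",
    "Violation",
    "ValidationReport",
    "parse_code_token",
    "render_code_token",
    "parse_profile",
    "validate_profile",
    "profile_from_dict",
    "profile_to_dict",
]

_CC_RE = re.compile(r"\(cc\)\s*$", re.IGNORECASE)
_BASE_RE = re.compile(r"^[A-Za-z]+$")


@dataclass(frozen=True)
class CodeInstance:
    """One occurrence of a consent code, with parameter and (CC) flag."""

    definition: CodeDefinition
    parameter: str | None = None
    cc: bool = False

    def __post_init__(self):
        if self.definition.parameterized and not self.parameter:
            raise ParameterArityError(
                self.definition.id,
                f"{self.definition.id}-[XX] requires a parameter",
            )
        if not self.definition.parameterized and self.parameter is not None:
            raise ParameterArityError(
                self.definition.id, "code takes no parameter"
            )
        if self.cc and not self.definition.cc_suffix_allowed:
            raise CCNotAllowedError(self.definition.id)

    @property
    def code(self) -> str:
        return self.definition.id

    @property
    def parameter_normalized(self) -> str | None:
        return None if self.parameter is None else normalize_term(self.parameter)

    @property
    def token(self) -> str:
        return render_code_token(self)

    # identity is (code, normalized parameter, cc); parameter case is
    # preserved for display but "DS-Cancer" and "DS-CANCER" are one instance
    def _key(self):
        return (self.definition.id, self.parameter_normalized, self.cc)

    def __eq__(self, other):
        return isinstance(other, CodeInstance) and self._key() == other._key()

    def __hash__(self):
        return hash(self._key())

    def __repr__(self):
        return f"CodeInstance({self.token!r})"


def parse_code_token(token: str) -> CodeInstance:
    """Parse one token like ``"DS-CANCER(CC)"`` into a :class:`CodeInstance`.

    Raises :class:`TokenSyntaxError`, :class:`UnknownCodeError`,
    :class:`ParameterArityError` or :class:`CCNotAllowedError`.
    """
    raw = token
    token = token.strip()
    if not token:
        raise TokenSyntaxError(raw, "empty token")
    cc = False
    m = _CC_RE.search(token)
    if m:
        cc = True
        token = token[: m.start()].rstrip()
    if "(" in token or ")" in token:
        raise TokenSyntaxError(raw, "unexpected parenthesis outside (CC) suffix")
    base, sep, param = token.partition("-")
    base = base.strip()
    if not _BASE_RE.match(base):
        raise TokenSyntaxError(raw, f"base code {base!r} is not alphabetic")
    param = param.strip() if sep else None
    if sep and not param:
        raise TokenSyntaxError(raw, "dangling '-' with empty parameter")
    definition = get_registry().get(base.upper())
    if definition.parameterized and param is None:
        raise ParameterArityError(
            definition.id, f"{definition.id}-[XX] requires a parameter"
        )
    if not definition.parameterized and param is not None:
        raise ParameterArityError(
            definition.id, f"unexpected parameter {param!r} (code takes none)"
        )
    return CodeInstance(definition=definition, parameter=param, cc=cc)


def render_code_token(instance: CodeInstance) -> str:
    """Canonical spelling; inverse of :func:`parse_code_token`."""
    out = instance.definition.id
    if instance.parameter is not None:
        out += f"-{instance.parameter}"
    if instance.cc:
        out += "(CC)"
    return out


def _instance_sort_key(inst: CodeInstance):
    return (inst.definition.row_order, inst.parameter_normalized or "", inst.cc)


@dataclass(frozen=True)
class ConsentProfile:
    """A validated set of code instances attached to one resource."""

    primary: CodeInstance
    secondaries: frozenset[CodeInstance] = frozenset()
    requirements: frozenset[CodeInstance] = frozenset()  # REQUIREMENT + PERMISSION
    resource_kind: frozenset[str] = frozenset({"data"})
    is_genetic_resource: bool = False
    approved_entities: Mapping[str, Sequence[str]] | None = None
    unknown_tokens: tuple[str, ...] = ()

    @property
    def tokens(self) -> list[str]:
        """Canonical token list, primary first then table order."""
        out = [self.primary.token]
        out += [i.token for i in sorted(self.secondaries, key=_instance_sort_key)]
        out += [i.token for i in sorted(self.requirements, key=_instance_sort_key)]
        out += list(self.unknown_tokens)
        return out

    @property
    def all_instances(self) -> list[CodeInstance]:
        return (
            [self.primary]
            + sorted(self.secondaries, key=_instance_sort_key)
            + sorted(self.requirements, key=_instance_sort_key)
        )

    def has(self, code_id: str) -> bool:
        return any(i.code == code_id for i in self.all_instances)

    def instances_of(self, code_id: str) -> list[CodeInstance]:
        return [i for i in self.all_instances if i.code == code_id]

    def __repr__(self):
        return f"ConsentProfile({' '.join(self.tokens)})"


@dataclass(frozen=True)
class Violation:
    rule_id: str
    severity: str  # "error" | "warning"
    message: str
    tokens: tuple[str, ...] = ()


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[Violation, ...] = ()

    @property
    def valid(self) -> bool:
        return not any(v.severity == "error" for v in self.violations)

    @property
    def errors(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "error"]

    @property
    def warnings(self) -> list[Violation]:
        return [v for v in self.violations if v.severity == "warning"]


def validate_profile(
    profile: ConsentProfile, *, allow_nres_companions: bool = False
) -> ValidationReport:
    """Structural validation; deterministic, never raises.

    ``allow_nres_companions`` relaxes the NRES_COMPANIONS rule for
    deployments that read the open-access category as still admitting
    requirement codes.
    """
    v: list[Violation] = []

    def err(rule, msg, *tokens):
        v.append(Violation(rule, "error", msg, tuple(tokens)))

    def warn(rule, msg, *tokens):
        v.append(Violation(rule, "warning", msg, tuple(tokens)))

    primary = profile.primary
    if primary.definition.tier is not Tier.PRIMARY:
        err(
            "SINGLE_PRIMARY",
            f"{primary.code} is not a primary category",
            primary.token,
        )

    companions = sorted(
        profile.secondaries | profile.requirements, key=_instance_sort_key
    )
    for inst in companions:
        if inst.definition.tier is Tier.PRIMARY:
            err(
                "SINGLE_PRIMARY",
                "a profile carries exactly one primary category",
                inst.token,
            )

    if primary.code == "NRES" and companions and not allow_nres_companions:
        err(
            "NRES_COMPANIONS",
            "NRES places no restrictions at all on use and admits no "
            "companion codes",
            *[i.token for i in companions],
        )

    for inst in companions:
        cid = inst.code
        if cid == "HPOA" and primary.code not in ("HMB", "DS"):
            err(
                "HPOA_SCOPE",
                "HPOA applies only to HMB and DS profiles",
                inst.token,
            )
        if inst.definition.genetic_only and not profile.is_genetic_resource:
            err(
                "GSO_SCOPE",
                f"{cid} applies only to genetic research datasets/biospecimens",
                inst.token,
            )
        if inst.definition.biospecimen_only and "biospecimen" not in profile.resource_kind:
            err(
                "BIOSPECIMEN_SCOPE",
                f"{cid} applies only to biospecimens",
                inst.token,
            )
        if not (inst.definition.applies_to & profile.resource_kind):
            warn(
                "APPLICABILITY",
                f"{cid} applies to {'/'.join(sorted(inst.definition.applies_to))} "
                f"but the resource is {'/'.join(sorted(profile.resource_kind))}",
                inst.token,
            )
        if cid == "TS":
            try:
                months = int(inst.parameter)  # type: ignore[arg-type]
                if months <= 0:
                    raise ValueError
            except (TypeError, ValueError):
                warn(
                    "TS_PARAM_FORMAT",
                    f"TS parameter {inst.parameter!r} is not a positive "
                    "integer month count; the TS gate will fail closed",
                    inst.token,
                )
        if cid == "MOR":
            import datetime

            try:
                datetime.date.fromisoformat(inst.parameter or "")
            except ValueError:
                warn(
                    "MOR_PARAM_FORMAT",
                    f"MOR parameter {inst.parameter!r} is not an ISO-8601 "
                    "date; the embargo date cannot be cross-checked",
                    inst.token,
                )

    if primary.code == "DS":
        for inst in companions:
            if inst.code == "NDS" and (
                inst.parameter_normalized == primary.parameter_normalized
            ):
                err(
                    "SELF_CONTRADICTION",
                    f"the only permitted disease ({primary.parameter}) is "
                    "also excluded; the permitted set is empty",
                    primary.token,
                    inst.token,
                )

    if primary.cc and any(i.code == "RUO" for i in companions):
        warn(
            "CC_RUO_REDUNDANT",
            "RUO excludes the clinical reference use that (CC) permits; "
            "the more restrictive RUO prevails",
            primary.token,
            "RUO",
        )

    for tok in profile.unknown_tokens:
        warn("UNKNOWN_CODE", f"unknown code {tok!r} carried opaquely", tok)

    return ValidationReport(tuple(v))


def parse_profile(
    tokens: Iterable[str],
    resource_kind: Iterable[str] = ("data",),
    is_genetic_resource: bool = False,
    approved_entities: Mapping[str, Sequence[str]] | None = None,
    *,
    permissive: bool = False,
    allow_nres_companions: bool = False,
) -> ConsentProfile:
    """Parse tokens into a validated :class:`ConsentProfile`.

    Unknown codes are hard errors unless ``permissive`` is set, in which case
    they are carried opaquely and reported as warnings. Raises
    :class:`ProfileValidationError` (report attached) on structural problems.
    """
    tokens = list(tokens)
    if not tokens:
        raise ProfileValidationError(
            ValidationReport(
                (Violation("SINGLE_PRIMARY", "error", "no codes given"),)
            )
        )
    instances: list[CodeInstance] = []
    unknown: list[str] = []
    for tok in tokens:
        try:
            instances.append(parse_code_token(tok))
        except UnknownCodeError:
            if permissive:
                unknown.append(tok.strip())
            else:
                raise
    primaries = [i for i in instances if i.definition.tier is Tier.PRIMARY]
    if len(primaries) != 1:
        raise ProfileValidationError(
            ValidationReport(
                (
                    Violation(
                        "SINGLE_PRIMARY",
                        "error",
                        f"a profile carries exactly one primary category "
                        f"(got {len(primaries)})",
                        tuple(i.token for i in primaries),
                    ),
                )
            )
        )
    profile = ConsentProfile(
        primary=primaries[0],
        secondaries=frozenset(
            i for i in instances if i.definition.tier is Tier.SECONDARY
        ),
        requirements=frozenset(
            i
            for i in instances
            if i.definition.tier in (Tier.REQUIREMENT, Tier.PERMISSION)
        ),
        resource_kind=frozenset(resource_kind),
        is_genetic_resource=is_genetic_resource,
        approved_entities=dict(approved_entities) if approved_entities else None,
        unknown_tokens=tuple(unknown),
    )
    report = validate_profile(profile, allow_nres_companions=allow_nres_companions)
    if not report.valid:
        raise ProfileValidationError(report)
    return profile


def profile_to_dict(profile: ConsentProfile) -> dict:
    return {
        "codes": profile.tokens,
        "resource_kind": sorted(profile.resource_kind),
        "is_genetic_resource": profile.is_genetic_resource,
        "approved_entities": (
            {k: list(vv) for k, vv in profile.approved_entities.items()}
            if profile.approved_entities
            else None
        ),
    }


def profile_from_dict(d: Mapping, **kwargs) -> ConsentProfile:
    """Build a profile from the JSON exchange form ``{"codes": [...], ...}``."""
    if "codes" not in d or not isinstance(d["codes"], (list, tuple)):
        raise ProfileValidationError(
            ValidationReport(
                (Violation("SCHEMA", "error", 'profile JSON needs a "codes" list'),)
            )
        )
    return parse_profile(
        d["codes"],
        resource_kind=d.get("resource_kind", ("data",)),
        is_genetic_resource=bool(d.get("is_genetic_resource", False)),
        approved_entities=d.get("approved_entities"),
        **kwargs,
    )
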
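"""Access-decision engine.

Evaluates a structured research-use request against a consent profile and
returns PERMIT, PERMIT_WITH_OBLIGATIONS or DENY with an explainable trace.

The semantics follow the published primary/secondary region map:

* the primary category draws the permitted purpose region — NRES places no
  restrictions; GRU admits health, other biological and population
  origins/ancestry (POA) research; HMB admits health only; DS-[XX] admits
  health related to the named disease; POA admits ancestry research only;
* secondary codes are conjunctive modifiers — TDS/RS further require
  therapy/research-type match, NDS carves excluded diseases out of the
  region, NMDS excludes general methods-development research beyond what
  supports the permitted research, RUO excludes clinical reference use,
  GSO excludes purely non-genetic use, and HPOA adds health-related
  ancestry analysis to HMB/DS profiles;
* requirement codes split into fact gates checked against requester
  attributes (NPU, NCU, GS, TS, US, PS, IS) and attestation obligations
  that must be affirmed (PUB, COL, ROR, RTN, IRB, BEN, OS, MOR);
* permission codes (CQ, CS, CR, HR, ARA, GEN, CL) grant extras; the
  biospecimen intents cell-line derivation and nucleic-acid extraction are
  denied unless CL / GEN respectively are present.

Unattested obligations and unmet gates fail closed: the safe default for
consent is DENY, with reasons listing exactly what would flip the outcome.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Mapping

from .errors import MatcherRequiredError, ParameterArityError
from .parser import CodeInstance, ConsentProfile
from .registry import get_registry
from .terms import EXACT_MATCHER, RegionTable, TermMatcher

__all__ = [
    "PURPOSE_DOMAINS",
    "METHODS_DEV_LEVELS",
    "GATE_CODES",
    "OBLIGATION_CODES",
    "PERMISSION_CODES",
    "RequesterAttributes",
    "AccessRequest",
    "TraceEvent",
    "Decision",
    "EngineConfig",
    "purpose_permitted",
    "evaluate_gates",
    "evaluate",
    "explain",
    "STATUS_ORDER",
]

PURPOSE_DOMAINS = ("other_biological", "health", "poa")
METHODS_DEV_LEVELS = ("none", "within_bounds", "general")

#: fact gates: checked against requester attributes / request facts
GATE_CODES = ("NPU", "NCU", "GS", "TS", "US", "PS", "IS")
#: attestation obligations: must be affirmed by the requester
OBLIGATION_CODES = ("BEN", "PUB", "COL", "ROR", "RTN", "IRB", "MOR", "OS")
#: permissions granted by the resource
PERMISSION_CODES = ("CQ", "CS", "CR", "HR", "ARA", "GEN", "CL")

STATUS_ORDER = {"DENY": 0, "PERMIT_WITH_OBLIGATIONS": 1, "PERMIT": 2}


@dataclass(frozen=True)
class RequesterAttributes:
    org_type: Literal["for_profit", "not_for_profit"] = "not_for_profit"
    commercial_purpose: bool = False
    geography: str = ""
    user_id: str | None = None
    project_id: str | None = None
    institution_id: str | None = None
    planned_publication_date: datetime.date | None = None

    def __post_init__(self):
        if self.org_type not in ("for_profit", "not_for_profit"):
            raise ValueError(f"bad org_type {self.org_type!r}")


@dataclass(frozen=True)
class AccessRequest:
    """A structured research purpose plus requester facts and attestations."""

    purpose_domain: Literal["other_biological", "health", "poa"] = "health"
    disease_terms: frozenset[str] = frozenset()
    therapy_terms: frozenset[str] = frozenset()
    research_type_terms: frozenset[str] = frozenset()
    poa_health_related: bool = False
    methods_dev: Literal["none", "within_bounds", "general"] = "none"
    clinical_reference_use: bool = False
    uses_only_nongenetic_data: bool = False
    requester: RequesterAttributes = field(default_factory=RequesterAttributes)
    attestations: Mapping[str, bool] = field(default_factory=dict)
    biospecimen_intents: frozenset[str] = frozenset()
    duration_months: int | None = None

    def __post_init__(self):
        if self.purpose_domain not in PURPOSE_DOMAINS:
            raise ValueError(f"bad purpose_domain {self.purpose_domain!r}")
        if self.methods_dev not in METHODS_DEV_LEVELS:
            raise ValueError(f"bad methods_dev {self.methods_dev!r}")
        if self.duration_months is not None and self.duration_months <= 0:
            raise ValueError("duration_months must be positive when present")
        bad = set(self.biospecimen_intents) - {
            "derive_cell_lines",
            "extract_nucleic_acids",
        }
        if bad:
            raise ValueError(f"unknown biospecimen intents {sorted(bad)}")
        # normalize container types so callers may pass plain lists/dicts
        object.__setattr__(self, "disease_terms", frozenset(self.disease_terms))
        object.__setattr__(self, "therapy_terms", frozenset(self.therapy_terms))
        object.__setattr__(
            self, "research_type_terms", frozenset(self.research_type_terms)
        )
        object.__setattr__(
            self, "biospecimen_intents", frozenset(self.biospecimen_intents)
        )

    def to_dict(self) -> dict:
        r = self.requester
        return {
            "purpose_domain": self.purpose_domain,
            "disease_terms": sorted(self.disease_terms),
            "therapy_terms": sorted(self.therapy_terms),
            "research_type_terms": sorted(self.research_type_terms),
            "poa_health_related": self.poa_health_related,
            "methods_dev": self.methods_dev,
            "clinical_reference_use": self.clinical_reference_use,
            "uses_only_nongenetic_data": self.uses_only_nongenetic_data,
            "requester": {
                "org_type": r.org_type,
                "commercial_purpose": r.commercial_purpose,
                "geography": r.geography,
                "user_id": r.user_id,
                "project_id": r.project_id,
                "institution_id": r.institution_id,
                "planned_publication_date": (
                    r.planned_publication_date.isoformat()
                    if r.planned_publication_date
                    else None
                ),
            },
            "attestations": dict(self.attestations),
            "biospecimen_intents": sorted(self.biospecimen_intents),
            "duration_months": self.duration_months,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "AccessRequest":
        rd = dict(d.get("requester") or {})
        ppd = rd.get("planned_publication_date")
        if isinstance(ppd, str):
            rd["planned_publication_date"] = datetime.date.fromisoformat(ppd)
        requester = RequesterAttributes(**rd)
        kwargs = {k: v for k, v in d.items() if k != "requester"}
        return cls(requester=requester, **kwargs)


@dataclass(frozen=True)
class TraceEvent:
    rule_id: str
    code: str
    outcome: Literal["pass", "deny", "info"]
    message: str


@dataclass(frozen=True)
class Decision:
    status: Literal["PERMIT", "PERMIT_WITH_OBLIGATIONS", "DENY"]
    obligations: tuple[tuple[str, str | None], ...] = ()
    granted_permissions: tuple[str, ...] = ()
    denial_reasons: tuple[tuple[str, str, str], ...] = ()  # (rule, code, message)
    trace: tuple[TraceEvent, ...] = ()

    def __post_init__(self):
        if self.status == "PERMIT" and self.obligations:
            raise ValueError("PERMIT decisions carry no obligations")
        if self.status == "DENY" and not self.denial_reasons:
            raise ValueError("DENY decisions carry at least one reason")

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "obligations": [list(o) for o in self.obligations],
            "granted_permissions": list(self.granted_permissions),
            "denial_reasons": [list(r) for r in self.denial_reasons],
            "trace": [
                {
                    "rule_id": t.rule_id,
                    "code": t.code,
                    "outcome": t.outcome,
                    "message": t.message,
                }
                for t in self.trace
            ],
        }


@dataclass(frozen=True)
class EngineConfig:
    """Policy knobs for the points the code table leaves open.

    hpoa_requires_disease_match
        On a DS profile, HPOA-sanctioned health-related ancestry analysis
        must additionally match the DS disease (most restrictive reading).
    general_methods_primaries
        Primaries under which general methods-development research is
        acceptable when NMDS is absent (the general-methods region sits
        outside the HMB/DS/POA regions on the published map).
    """

    hpoa_requires_disease_match: bool = True
    general_methods_primaries: tuple[str, ...] = ("NRES", "GRU")


DEFAULT_CONFIG = EngineConfig()


@lru_cache(maxsize=1)
def default_region_table() -> RegionTable:
    return RegionTable.packaged()


def _sorted_instances(instances) -> list[CodeInstance]:
    return sorted(
        instances,
        key=lambda i: (i.definition.row_order, i.parameter_normalized or ""),
    )


def _all_match(terms, parameter, matcher: TermMatcher) -> bool:
    return bool(terms) and all(matcher.matches(t, parameter) for t in terms)


def purpose_permitted(
    primary: CodeInstance,
    secondaries,
    request: AccessRequest,
    term_matcher: TermMatcher | None = None,
    config: EngineConfig = DEFAULT_CONFIG,
):
    """Is the request's purpose inside the primary region after applying all
    secondary modifiers conjunctively?

    Returns ``(permitted, denial_reasons, trace)``. Region denials carry the
    primary's code; secondary vetoes carry the secondary's code.
    """
    secondaries = _sorted_instances(secondaries)
    needs_matcher = primary.definition.parameterized or any(
        s.definition.parameterized for s in secondaries
    )
    if term_matcher is None:
        if needs_matcher:
            raise MatcherRequiredError(
                "a term matcher is required to evaluate parameterized codes"
            )
        term_matcher = EXACT_MATCHER

    reasons: list[tuple[str, str, str]] = []
    trace: list[TraceEvent] = []
    sec_ids = {s.code for s in secondaries}

    def deny(rule, code, msg):
        reasons.append((rule, code, msg))
        trace.append(TraceEvent(rule, code, "deny", msg))

    def ok(rule, code, msg):
        trace.append(TraceEvent(rule, code, "pass", msg))

    base = primary.code
    dom = request.purpose_domain

    if base == "NRES":
        ok("NRES_OPEN", "NRES", "no restrictions on use")
    elif base == "GRU":
        ok("PRIMARY_DOMAIN", "GRU", f"{dom} research is within general research use")
    elif base == "HMB":
        if dom == "health":
            ok("PRIMARY_DOMAIN", "HMB", "health/medical/biomedical purpose")
        elif dom == "poa" and "HPOA" in sec_ids and request.poa_health_related:
            ok(
                "HPOA_HEALTH_POA",
                "HPOA",
                "health-related population origins/ancestry analysis",
            )
        else:
            deny(
                "PRIMARY_DOMAIN",
                "HMB",
                f"{dom} purpose is outside health/medical/biomedical use"
                + (
                    " (ancestry analysis requires HPOA and a health-related "
                    "context)"
                    if dom == "poa"
                    else ""
                ),
            )
    elif base == "DS":
        disease_ok = _all_match(
            request.disease_terms, primary.parameter, term_matcher
        )
        if dom == "health":
            if disease_ok:
                ok(
                    "DS_DISEASE_MATCH",
                    "DS",
                    f"study diseases fall under {primary.parameter}",
                )
            else:
                deny(
                    "DS_DISEASE_MATCH",
                    "DS",
                    f"use must be related to {primary.parameter}",
                )
        elif dom == "poa" and "HPOA" in sec_ids and request.poa_health_related:
            if disease_ok or not config.hpoa_requires_disease_match:
                ok(
                    "HPOA_HEALTH_POA",
                    "HPOA",
                    "health-related ancestry analysis within the disease area",
                )
            else:
                deny(
                    "DS_DISEASE_MATCH",
                    "DS",
                    "health-related ancestry analysis must still relate to "
                    f"{primary.parameter}",
                )
        else:
            deny(
                "PRIMARY_DOMAIN",
                "DS",
                f"{dom} purpose is outside disease-specific use",
            )
    elif base == "POA":
        if dom == "poa":
            ok("PRIMARY_DOMAIN", "POA", "population origins/ancestry study")
        else:
            deny(
                "PRIMARY_DOMAIN",
                "POA",
                "use is limited to the study of population origins or ancestry",
            )
    else:  # pragma: no cover - registry guarantees five primaries
        deny("PRIMARY_DOMAIN", base, f"unrecognized primary {base}")

    for inst in secondaries:
        cid = inst.code
        if cid == "TDS":
            if _all_match(request.therapy_terms, inst.parameter, term_matcher):
                ok("TDS_MATCH", "TDS", f"study relates to {inst.parameter}")
            else:
                deny(
                    "TDS_MATCH",
                    "TDS",
                    f"use must be related to {inst.parameter}",
                )
        elif cid == "RS":
            if _all_match(
                request.research_type_terms, inst.parameter, term_matcher
            ):
                ok("RS_MATCH", "RS", f"study is of type {inst.parameter}")
            else:
                deny(
                    "RS_MATCH",
                    "RS",
                    f"use is limited to studies of {inst.parameter}",
                )
        elif cid == "NDS":
            hits = sorted(
                t
                for t in request.disease_terms
                if term_matcher.matches(t, inst.parameter)
            )
            if hits:
                deny(
                    "NDS_EXCLUDED",
                    "NDS",
                    f"research into {inst.parameter} is excluded "
                    f"(matched: {', '.join(hits)})",
                )
            else:
                ok("NDS_EXCLUDED", "NDS", f"no excluded {inst.parameter} research")
        elif cid == "NMDS":
            if request.methods_dev == "general":
                deny(
                    "NMDS_GENERAL",
                    "NMDS",
                    "methods development is permitted only within the bounds "
                    "of the other use limitations",
                )
            else:
                ok("NMDS_GENERAL", "NMDS", "no general methods development")
        elif cid == "GSO":
            if request.uses_only_nongenetic_data:
                deny(
                    "GSO_GENETIC_ONLY",
                    "GSO",
                    "use is limited to genetic studies only",
                )
            else:
                ok("GSO_GENETIC_ONLY", "GSO", "genetic study")
        # HPOA and RUO act through the primary-region and clinical-use rules

    if (
        request.methods_dev == "general"
        and "NMDS" not in sec_ids
        and base not in config.general_methods_primaries
    ):
        deny(
            "METHODS_GENERAL",
            base,
            "general methods-development research lies outside the "
            f"{base} region",
        )

    return (not reasons, reasons, trace)


def evaluate_gates(
    requirements,
    request: AccessRequest,
    region_table: RegionTable | None = None,
    approved_entities: Mapping | None = None,
):
    """Check the fact gates; returns ``(failures, trace)``.

    One failure record per unmet fact-checkable requirement.
    """
    if region_table is None:
        region_table = default_region_table()
    failures: list[tuple[str, str, str]] = []
    trace: list[TraceEvent] = []
    r = request.requester
    approved = approved_entities or {}

    def fail(rule, code, msg):
        failures.append((rule, code, msg))
        trace.append(TraceEvent(rule, code, "deny", msg))

    def ok(rule, code, msg):
        trace.append(TraceEvent(rule, code, "pass", msg))

    for inst in _sorted_instances(requirements):
        cid = inst.code
        if cid == "NPU":
            if r.org_type != "not_for_profit":
                fail("GATE_NPU", "NPU", "use is limited to not-for-profit organizations")
            else:
                ok("GATE_NPU", "NPU", "not-for-profit requester")
        elif cid == "NCU":
            if r.commercial_purpose:
                fail("GATE_NCU", "NCU", "use is limited to non-commercial uses")
            else:
                ok("GATE_NCU", "NCU", "non-commercial purpose")
        elif cid == "GS":
            if r.geography and region_table.contains(inst.parameter, r.geography):
                ok("GATE_GS", "GS", f"{r.geography} is within {inst.parameter}")
            else:
                fail(
                    "GATE_GS",
                    "GS",
                    f"use is limited to within {inst.parameter} "
                    f"(requester geography: {r.geography or 'unspecified'})",
                )
        elif cid == "TS":
            try:
                months = int(inst.parameter)  # type: ignore[arg-type]
                if months <= 0:
                    raise ValueError
            except (TypeError, ValueError):
                raise ParameterArityError(
                    "TS",
                    f"unparseable TS parameter {inst.parameter!r}: expected "
                    "an integer number of months",
                ) from None
            if request.duration_months is None:
                fail(
                    "GATE_TS",
                    "TS",
                    f"use is approved for {months} months but the request "
                    "states no duration",
                )
            elif request.duration_months > months:
                fail(
                    "GATE_TS",
                    "TS",
                    f"requested {request.duration_months} months exceeds the "
                    f"{months}-month approval",
                )
            else:
                ok("GATE_TS", "TS", f"{request.duration_months} ≤ {months} months")
        elif cid in ("US", "PS", "IS"):
            key, ident = {
                "US": ("users", r.user_id),
                "PS": ("projects", r.project_id),
                "IS": ("institutions", r.institution_id),
            }[cid]
            allowed = approved.get(key)
            if not allowed:
                fail(
                    f"GATE_{cid}",
                    cid,
                    f"{cid} requires named approval but the resource lists "
                    f"no approved {key}",
                )
            elif ident is None or ident not in allowed:
                fail(
                    f"GATE_{cid}",
                    cid,
                    f"requester {key[:-1]} {ident!r} is not among the "
                    f"approved {key}",
                )
            else:
                ok(f"GATE_{cid}", cid, f"{ident} is approved")
    return failures, trace


def _parse_iso_date(s: str | None) -> datetime.date | None:
    if not s:
        return None
    try:
        return datetime.date.fromisoformat(s)
    except ValueError:
        return None


def evaluate(
    profile: ConsentProfile,
    request: AccessRequest,
    term_matcher: TermMatcher | None = None,
    region_table: RegionTable | None = None,
    config: EngineConfig = DEFAULT_CONFIG,
) -> Decision:
    """Full decision for one (profile, request) pair.

    Deterministic: identical inputs give identical decisions and traces.
    """
    if term_matcher is None:
        term_matcher = EXACT_MATCHER
    if region_table is None:
        region_table = default_region_table()

    if profile.primary.code == "NRES":
        ev = TraceEvent("NRES_OPEN", "NRES", "pass", "no restrictions on data use")
        return Decision(status="PERMIT", trace=(ev,))

    reasons: list[tuple[str, str, str]] = []
    trace: list[TraceEvent] = []

    ok_purpose, purpose_reasons, purpose_trace = purpose_permitted(
        profile.primary, profile.secondaries, request, term_matcher, config
    )
    reasons += purpose_reasons
    trace += purpose_trace

    sec_ids = {s.code for s in profile.secondaries}
    if request.clinical_reference_use:
        if "RUO" in sec_ids:
            msg = "research use only: no use in clinical care as reference data"
            reasons.append(("RUO_NO_CLINICAL", "RUO", msg))
            trace.append(TraceEvent("RUO_NO_CLINICAL", "RUO", "deny", msg))
        elif not profile.primary.cc:
            msg = (
                "clinical reference use requires the (CC) permission on "
                f"{profile.primary.code}"
            )
            reasons.append(("CC_REQUIRED", profile.primary.code, msg))
            trace.append(
                TraceEvent("CC_REQUIRED", profile.primary.code, "deny", msg)
            )
        else:
            trace.append(
                TraceEvent(
                    "CC_REQUIRED",
                    profile.primary.code,
                    "pass",
                    "clinical reference use permitted by (CC)",
                )
            )

    gate_failures, gate_trace = evaluate_gates(
        profile.requirements, request, region_table, profile.approved_entities
    )
    reasons += gate_failures
    trace += gate_trace

    obligations: list[tuple[str, str | None]] = []
    for inst in _sorted_instances(profile.requirements):
        cid = inst.code
        if cid not in OBLIGATION_CODES:
            continue
        obligations.append((cid, inst.parameter))
        if not request.attestations.get(cid, False):
            msg = (
                f"attestation to {inst.token} "
                f"({inst.definition.name}) is required but not given"
            )
            reasons.append(("OBLIGATION_UNATTESTED", cid, msg))
            trace.append(TraceEvent("OBLIGATION_UNATTESTED", cid, "deny", msg))
        else:
            trace.append(
                TraceEvent(
                    "OBLIGATION_ATTESTED", cid, "pass", f"{inst.token} attested"
                )
            )
            if cid == "MOR":
                embargo = _parse_iso_date(inst.parameter)
                planned = request.requester.planned_publication_date
                if embargo and planned and planned < embargo:
                    msg = (
                        f"planned publication {planned.isoformat()} precedes "
                        f"the {embargo.isoformat()} embargo"
                    )
                    reasons.append(("MOR_DATE_CONFLICT", "MOR", msg))
                    trace.append(
                        TraceEvent("MOR_DATE_CONFLICT", "MOR", "deny", msg)
                    )

    perm_ids = {i.code for i in profile.requirements}
    for intent, needed in (
        ("derive_cell_lines", "CL"),
        ("extract_nucleic_acids", "GEN"),
    ):
        if intent in request.biospecimen_intents and needed not in perm_ids:
            msg = f"{intent} requires the {needed} permission code"
            reasons.append((f"PERMISSION_{needed}_REQUIRED", needed, msg))
            trace.append(
                TraceEvent(f"PERMISSION_{needed}_REQUIRED", needed, "deny", msg)
            )

    granted = tuple(c for c in PERMISSION_CODES if c in perm_ids)

    if reasons:
        status = "DENY"
    elif obligations:
        status = "PERMIT_WITH_OBLIGATIONS"
    else:
        status = "PERMIT"
    return Decision(
        status=status,
        obligations=tuple(obligations) if status != "PERMIT" else (),
        granted_permissions=granted,
        denial_reasons=tuple(reasons),
        trace=tuple(trace),
    )


def explain(decision: Decision) -> str:
    """Render the rule trace, citing each code's registry description."""
    registry = get_registry()
    lines = [f"decision: {decision.status}"]
    for ev in decision.trace:
        desc = ""
        if ev.code in registry:
            desc = f" — {registry.get(ev.code).description}"
        mark = {"pass": "✓", "deny": "✗", "info": "·"}[ev.outcome]
        lines.append(f"  {mark} [{ev.rule_id}] {ev.code}: {ev.message}{desc}")
    if decision.obligations:
        lines.append(
            "obligations: "
            + ", ".join(c + (f"-{p}" if p else "") for c, p in decision.obligations)
        )
    if decision.granted_permissions:
        lines.append("permissions: " + ", ".join(decision.granted_permissions))
    for rule, code, msg in decision.denial_reasons:
        lines.append(f"denied [{rule}] {code}: {msg}")
    return "\n".join(lines)
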
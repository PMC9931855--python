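"""Synthetic profiles/requests and an independent brute-force oracle.

Everything the test suite needs is generated here, seeded and deterministic:

* :func:`request_grid` — the finite enumeration of canonical access
  requests spanning every purpose axis (1296 combinations);
* :func:`enumerate_profile_grid` — all valid profiles with bounded numbers
  of companion codes and placeholder parameters;
* :func:`random_profile` / :func:`random_request` — seeded generators;
* :func:`oracle_evaluate` — a deliberately naive re-implementation of the
  decision semantics as straight-line conditionals, one branch per code
  table row, sharing no evaluation logic with :mod:`consentcodes.engine`
  (only the data tables and the plumbing dataclasses). Its whole purpose
  is to disagree with the engine if either is wrong.
"""

from __future__ import annotations

import itertools
import json
import random
from datetime import date
from typing import Iterable

from .engine import AccessRequest, Decision, RequesterAttributes, TraceEvent
from .parser import (
    CodeInstance,
    ConsentProfile,
    parse_code_token,
    validate_profile,
)
from .registry import ParameterRole, Tier, get_registry
from .terms import RegionTable

__all__ = [
    "PLACEHOLDER_PARAMS",
    "request_grid",
    "enumerate_profile_grid",
    "random_profile",
    "random_request",
    "oracle_evaluate",
    "decision_key",
    "emit",
]

#: canonical placeholder parameter per role, used by the profile grid
PLACEHOLDER_PARAMS = {
    ParameterRole.DISEASE: "X",
    ParameterRole.THERAPY_OR_DRUG: "X",
    ParameterRole.RESEARCH_TYPE: "X",
    ParameterRole.INVESTIGATORS: "X",
    ParameterRole.ROR_POLICY: "X",
    ParameterRole.GEOGRAPHIC_REGION: "X",
    ParameterRole.REPOSITORY_LINK: "X",
    ParameterRole.MONTHS: "12",
    ParameterRole.DATE: "2100-01-01",
}

_ATTESTABLE = ("BEN", "PUB", "COL", "ROR", "RTN", "IRB", "MOR", "OS")

_REQUESTERS = {
    "non_profit": RequesterAttributes(
        org_type="not_for_profit",
        commercial_purpose=False,
        geography="X",
        user_id="u1",
        project_id="p1",
        institution_id="i1",
    ),
    "for_profit_research": RequesterAttributes(
        org_type="for_profit",
        commercial_purpose=False,
        geography="X",
        user_id="u1",
        project_id="p1",
        institution_id="i1",
    ),
    "for_profit_commercial": RequesterAttributes(
        org_type="for_profit",
        commercial_purpose=True,
        geography="Y",
        user_id="u2",
        project_id="p2",
        institution_id="i2",
    ),
}

_TERM_SETS = {"match": frozenset({"X"}), "mismatch": frozenset({"Y"}), "none": frozenset()}


def request_grid() -> list[AccessRequest]:
    """The canonical request enumeration: 3 purpose domains × 3 term-match
    levels × 2 ancestry-health flags × 3 methods levels × 2 clinical-use
    flags × 2 genetic-use flags × 3 requester archetypes × 2 attestation
    archetypes = 1296 requests.

    The term-match level is applied to disease, therapy and research-type
    terms alike, so DS/NDS/TDS/RS are all exercised against the grid's
    placeholder parameter "X".
    """
    grid = []
    for (
        domain,
        match,
        poa_health,
        methods,
        clinical,
        nongenetic,
        requester,
        attested,
    ) in itertools.product(
        ("other_biological", "health", "poa"),
        ("match", "mismatch", "none"),
        (False, True),
        ("none", "within_bounds", "general"),
        (False, True),
        (False, True),
        ("non_profit", "for_profit_research", "for_profit_commercial"),
        (True, False),
    ):
        terms = _TERM_SETS[match]
        grid.append(
            AccessRequest(
                purpose_domain=domain,
                disease_terms=terms,
                therapy_terms=terms,
                research_type_terms=terms,
                poa_health_related=poa_health,
                methods_dev=methods,
                clinical_reference_use=clinical,
                uses_only_nongenetic_data=nongenetic,
                requester=_REQUESTERS[requester],
                attestations={c: True for c in _ATTESTABLE} if attested else {},
                duration_months=6,
            )
        )
    return grid


def _placeholder_instance(code_id: str, cc: bool = False) -> CodeInstance:
    d = get_registry().get(code_id)
    param = PLACEHOLDER_PARAMS.get(d.parameter_role)
    return CodeInstance(definition=d, parameter=param, cc=cc)


def _subsets(pool: list, max_size: int):
    for k in range(max_size + 1):
        yield from itertools.combinations(pool, k)


def enumerate_profile_grid(
    max_secondaries: int = 1,
    max_requirements: int = 1,
    requirement_pool: Iterable[str] | None = None,
) -> list[ConsentProfile]:
    """All valid profiles with at most the given numbers of secondary and
    requirement/permission companions, placeholder parameters, and both
    (CC) variants of the primaries that admit the flag.

    Profiles are built on a genetic data+biospecimen resource so every code
    is admissible; invalid combinations (two primaries are impossible by
    construction; NRES companions, HPOA off HMB/DS, DS-X with NDS-X) are
    dropped by re-validation.
    """
    registry = get_registry()
    primaries: list[CodeInstance] = []
    for d in registry.list(Tier.PRIMARY):
        primaries.append(_placeholder_instance(d.id))
        if d.cc_suffix_allowed:
            primaries.append(_placeholder_instance(d.id, cc=True))
    secondary_pool = [
        _placeholder_instance(d.id) for d in registry.list(Tier.SECONDARY)
    ]
    if requirement_pool is None:
        requirement_pool = [
            d.id
            for d in registry
            if d.tier in (Tier.REQUIREMENT, Tier.PERMISSION)
        ]
    req_pool = [_placeholder_instance(c) for c in requirement_pool]

    out: list[ConsentProfile] = []
    seen: set[tuple] = set()
    for primary in primaries:
        for secs in _subsets(secondary_pool, max_secondaries):
            for reqs in _subsets(req_pool, max_requirements):
                profile = ConsentProfile(
                    primary=primary,
                    secondaries=frozenset(secs),
                    requirements=frozenset(reqs),
                    resource_kind=frozenset({"data", "biospecimen"}),
                    is_genetic_resource=True,
                )
                key = tuple(profile.tokens)
                if key in seen:
                    continue
                seen.add(key)
                if validate_profile(profile).valid:
                    out.append(profile)
    return out


_PARAM_VOCAB = {
    ParameterRole.DISEASE: ["CANCER", "HIV", "ALS", "DIABETES"],
    ParameterRole.THERAPY_OR_DRUG: ["METFORMIN", "GENE THERAPY"],
    ParameterRole.RESEARCH_TYPE: ["PEDIATRIC", "AGING"],
    ParameterRole.INVESTIGATORS: ["SMITH LAB"],
    ParameterRole.ROR_POLICY: ["ACTIONABLE FINDINGS"],
    ParameterRole.GEOGRAPHIC_REGION: ["EU", "AFRICA", "NORTH_AMERICA"],
    ParameterRole.MONTHS: ["12", "24", "60"],
    ParameterRole.DATE: ["2027-01-01", "2030-06-30"],
    ParameterRole.REPOSITORY_LINK: ["biobank.example.org"],
}


def random_profile(seed: int, constraints: dict | None = None) -> ConsentProfile:
    """A valid random profile, a pure function of its seed.

    ``constraints`` may fix ``primary`` (code id), ``cc`` (bool),
    ``max_secondaries`` and ``max_requirements``.
    """
    constraints = constraints or {}
    rng = random.Random(seed)
    registry = get_registry()

    def instance(code_id, cc=False):
        d = registry.get(code_id)
        param = None
        if d.parameterized:
            param = rng.choice(_PARAM_VOCAB[d.parameter_role])
        return CodeInstance(definition=d, parameter=param, cc=cc)

    for _ in range(100):
        pid = constraints.get(
            "primary", rng.choice([d.id for d in registry.list(Tier.PRIMARY)])
        )
        d = registry.get(pid)
        cc = constraints.get("cc", rng.random() < 0.5) if d.cc_suffix_allowed else False
        primary = instance(pid, cc=cc)
        if pid == "NRES":
            n_sec = n_req = 0
        else:
            n_sec = rng.randint(0, constraints.get("max_secondaries", 2))
            n_req = rng.randint(0, constraints.get("max_requirements", 3))
        sec_ids = rng.sample([x.id for x in registry.list(Tier.SECONDARY)], n_sec)
        req_ids = rng.sample(
            [
                x.id
                for x in registry
                if x.tier in (Tier.REQUIREMENT, Tier.PERMISSION)
            ],
            n_req,
        )
        profile = ConsentProfile(
            primary=primary,
            secondaries=frozenset(instance(c) for c in sec_ids),
            requirements=frozenset(instance(c) for c in req_ids),
            resource_kind=frozenset({"data", "biospecimen"}),
            is_genetic_resource=True,
            approved_entities={"users": ["u1"], "projects": ["p1"], "institutions": ["i1"]},
        )
        if validate_profile(profile).valid:
            return profile
    raise ValueError(f"unsatisfiable profile constraints {constraints!r}")


def random_request(seed: int) -> AccessRequest:
    """A well-formed random request, a pure function of its seed."""
    rng = random.Random(seed ^ 0x5EED)
    terms = lambda vocab: frozenset(rng.sample(vocab, rng.randint(0, 2)))
    return AccessRequest(
        purpose_domain=rng.choice(["other_biological", "health", "poa"]),
        disease_terms=terms(_PARAM_VOCAB[ParameterRole.DISEASE]),
        therapy_terms=terms(_PARAM_VOCAB[ParameterRole.THERAPY_OR_DRUG]),
        research_type_terms=terms(_PARAM_VOCAB[ParameterRole.RESEARCH_TYPE]),
        poa_health_related=rng.random() < 0.5,
        methods_dev=rng.choice(["none", "within_bounds", "general"]),
        clinical_reference_use=rng.random() < 0.3,
        uses_only_nongenetic_data=rng.random() < 0.3,
        requester=RequesterAttributes(
            org_type=rng.choice(["for_profit", "not_for_profit"]),
            commercial_purpose=rng.random() < 0.3,
            geography=rng.choice(["FR", "US", "ZA", "JP", "X"]),
            user_id=rng.choice(["u1", "u2", None]),
            project_id=rng.choice(["p1", "p2", None]),
            institution_id=rng.choice(["i1", "i2", None]),
            planned_publication_date=rng.choice(
                [None, date(2026, 6, 1), date(2031, 1, 1)]
            ),
        ),
        attestations={c: rng.random() < 0.7 for c in _ATTESTABLE},
        biospecimen_intents=frozenset(
            rng.sample(["derive_cell_lines", "extract_nucleic_acids"], rng.randint(0, 2))
        ),
        duration_months=rng.choice([None, 6, 18, 48]),
    )


# --------------------------------------------------------------------------
# the brute-force oracle
# --------------------------------------------------------------------------

def _norm(s: str) -> str:
    return " ".join(s.lower().split())


def _term_under(term: str, param: str, matcher) -> bool:
    # matcher is only consulted for its hierarchy data; with none given the
    # oracle falls back to its own normalized equality
    if matcher is not None:
        return matcher.matches(term, param)
    return _norm(term) == _norm(param)


def oracle_evaluate(
    profile: ConsentProfile,
    request: AccessRequest,
    term_matcher=None,
    region_table: RegionTable | None = None,
) -> Decision:
    """Reference decision computed by one literal conditional per code.

    Structurally independent of :func:`consentcodes.engine.evaluate`; shares
    only the data tables (registry, region membership) and the Decision
    container.
    """
    if region_table is None:
        region_table = RegionTable.packaged()

    prim = profile.primary.code
    if prim == "NRES":
        return Decision(
            status="PERMIT",
            trace=(TraceEvent("NRES_OPEN", "NRES", "pass", "open access"),),
        )

    denies: list[tuple[str, str, str]] = []
    secs = sorted(profile.secondaries, key=lambda i: i.token)
    reqs = sorted(profile.requirements, key=lambda i: i.token)
    has_hpoa = any(s.code == "HPOA" for s in secs)
    has_ruo = any(s.code == "RUO" for s in secs)
    has_nmds = any(s.code == "NMDS" for s in secs)

    # --- primary region, one branch per table row -------------------------
    if prim == "GRU":
        pass  # health, other biological and POA research all permitted
    if prim == "HMB":
        if request.purpose_domain == "other_biological":
            denies.append(("O_HMB", "HMB", "not health-related"))
        if request.purpose_domain == "poa":
            if not (has_hpoa and request.poa_health_related):
                denies.append(("O_HMB_POA", "HMB", "POA not included"))
    if prim == "DS":
        dparam = profile.primary.parameter
        all_in = bool(request.disease_terms) and all(
            _term_under(t, dparam, term_matcher) for t in request.disease_terms
        )
        if request.purpose_domain == "other_biological":
            denies.append(("O_DS", "DS", "not disease research"))
        if request.purpose_domain == "health" and not all_in:
            denies.append(("O_DS_MATCH", "DS", "disease mismatch"))
        if request.purpose_domain == "poa":
            if not (has_hpoa and request.poa_health_related):
                denies.append(("O_DS_POA", "DS", "POA not included"))
            elif not all_in:
                denies.append(("O_DS_POA_MATCH", "DS", "disease mismatch"))
    if prim == "POA":
        if request.purpose_domain != "poa":
            denies.append(("O_POA", "POA", "POA research only"))

    # --- secondary modifiers ---------------------------------------------
    for s in secs:
        if s.code == "TDS":
            if not (
                request.therapy_terms
                and all(
                    _term_under(t, s.parameter, term_matcher)
                    for t in request.therapy_terms
                )
            ):
                denies.append(("O_TDS", "TDS", "therapy mismatch"))
        if s.code == "RS":
            if not (
                request.research_type_terms
                and all(
                    _term_under(t, s.parameter, term_matcher)
                    for t in request.research_type_terms
                )
            ):
                denies.append(("O_RS", "RS", "research-type mismatch"))
        if s.code == "NDS":
            if any(
                _term_under(t, s.parameter, term_matcher)
                for t in request.disease_terms
            ):
                denies.append(("O_NDS", "NDS", "excluded disease"))
        if s.code == "NMDS":
            if request.methods_dev == "general":
                denies.append(("O_NMDS", "NMDS", "general methods excluded"))
        if s.code == "GSO":
            if request.uses_only_nongenetic_data:
                denies.append(("O_GSO", "GSO", "non-genetic use excluded"))

    if request.methods_dev == "general" and not has_nmds:
        if prim in ("HMB", "DS", "POA"):
            denies.append(("O_METHODS", prim, "general methods outside region"))

    # --- clinical reference use ------------------------------------------
    if request.clinical_reference_use:
        if has_ruo:
            denies.append(("O_RUO", "RUO", "clinical reference use excluded"))
        elif not profile.primary.cc:
            denies.append(("O_CC", prim, "(CC) not granted"))

    # --- fact gates -------------------------------------------------------
    rq = request.requester
    approved = profile.approved_entities or {}
    for i in reqs:
        if i.code == "NPU" and rq.org_type == "for_profit":
            denies.append(("O_NPU", "NPU", "for-profit requester"))
        if i.code == "NCU" and rq.commercial_purpose:
            denies.append(("O_NCU", "NCU", "commercial purpose"))
        if i.code == "GS":
            if not (
                rq.geography
                and region_table.contains(i.parameter, rq.geography)
            ):
                denies.append(("O_GS", "GS", "outside region"))
        if i.code == "TS":
            if request.duration_months is None or request.duration_months > int(
                i.parameter
            ):
                denies.append(("O_TS", "TS", "duration exceeds approval"))
        if i.code == "US":
            if rq.user_id is None or rq.user_id not in (approved.get("users") or []):
                denies.append(("O_US", "US", "user not approved"))
        if i.code == "PS":
            if rq.project_id is None or rq.project_id not in (
                approved.get("projects") or []
            ):
                denies.append(("O_PS", "PS", "project not approved"))
        if i.code == "IS":
            if rq.institution_id is None or rq.institution_id not in (
                approved.get("institutions") or []
            ):
                denies.append(("O_IS", "IS", "institution not approved"))

    # --- attestation obligations -----------------------------------------
    obligations: list[tuple[str, str | None]] = []
    for i in reqs:
        if i.code in ("BEN", "PUB", "COL", "ROR", "RTN", "IRB", "MOR", "OS"):
            obligations.append((i.code, i.parameter))
            if not request.attestations.get(i.code, False):
                denies.append(("O_ATTEST", i.code, "not attested"))
            elif i.code == "MOR" and rq.planned_publication_date is not None:
                try:
                    embargo = date.fromisoformat(i.parameter or "")
                except ValueError:
                    embargo = None
                if embargo and rq.planned_publication_date < embargo:
                    denies.append(("O_MOR_DATE", "MOR", "publication before embargo"))

    # --- biospecimen permissions -----------------------------------------
    req_ids = {i.code for i in reqs}
    if "derive_cell_lines" in request.biospecimen_intents and "CL" not in req_ids:
        denies.append(("O_CL", "CL", "cell-line derivation not permitted"))
    if (
        "extract_nucleic_acids" in request.biospecimen_intents
        and "GEN" not in req_ids
    ):
        denies.append(("O_GEN", "GEN", "nucleic-acid extraction not permitted"))

    granted = tuple(
        c for c in ("CQ", "CS", "CR", "HR", "ARA", "GEN", "CL") if c in req_ids
    )
    if denies:
        status = "DENY"
    elif obligations:
        status = "PERMIT_WITH_OBLIGATIONS"
    else:
        status = "PERMIT"
    return Decision(
        status=status,
        obligations=tuple(obligations) if status != "PERMIT" else (),
        granted_permissions=granted,
        denial_reasons=tuple(denies),
    )


def decision_key(d: Decision) -> tuple:
    """Comparison key for engine↔oracle equivalence: status, sorted
    obligations, sorted set of denial-reason consent codes."""
    return (
        d.status,
        tuple(sorted((c, p or "") for c, p in d.obligations)),
        tuple(sorted({code for _, code, _ in d.denial_reasons})),
        tuple(sorted(d.granted_permissions)),
    )


def emit(seed: int, n_profiles: int, n_requests: int) -> dict:
    """A reproducible synthetic catalog + request set, as JSON-ready dicts."""
    from .parser import profile_to_dict

    datasets = []
    for k in range(n_profiles):
        p = random_profile(seed * 10_000 + k)
        datasets.append(
            {"dataset_id": f"DS{k:04d}", "title": f"synthetic dataset {k}"}
            | profile_to_dict(p)
            | {"profile_tokens": p.tokens}
        )
    requests = [
        random_request(seed * 20_000 + k).to_dict() for k in range(n_requests)
    ]
    return {"seed": seed, "catalog": {"datasets": datasets}, "requests": requests}


def emit_json(seed: int, n_profiles: int, n_requests: int) -> str:
    return json.dumps(emit(seed, n_profiles, n_requests), indent=2)
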
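"""Decision semantics: purpose regions, secondary modifiers, gates,
obligations, permissions, and the explainable trace."""

import datetime

import pytest

from consentcodes import (
    AccessRequest,
    EngineConfig,
    RequesterAttributes,
    TermMatcher,
    evaluate,
    evaluate_gates,
    explain,
    parse_profile,
    purpose_permitted,
)
from consentcodes.errors import MatcherRequiredError, ParameterArityError


def prof(*tokens, **kw):
    kw.setdefault("resource_kind", ("data", "biospecimen"))
    kw.setdefault("is_genetic_resource", True)
    return parse_profile(list(tokens), **kw)


def req(**kw):
    return AccessRequest(**kw)


# ---------------------------------------------------------------- purposes
@pytest.mark.parametrize(
    "tokens,request_kw,permitted",
    [
        (["HMB(CC)"], dict(purpose_domain="poa"), False),
        (["HMB(CC)", "HPOA"], dict(purpose_domain="poa", poa_health_related=True), True),
        (["HMB(CC)", "HPOA"], dict(purpose_domain="poa", poa_health_related=False), False),
        (["HMB(CC)"], dict(purpose_domain="other_biological"), False),
        (["GRU(CC)"], dict(purpose_domain="poa"), True),
        (["GRU(CC)"], dict(purpose_domain="other_biological"), True),
        (["GRU(CC)", "NDS-HIV"], dict(purpose_domain="health", disease_terms={"HIV"}), False),
        (["GRU(CC)", "NDS-HIV"], dict(purpose_domain="health", disease_terms={"CANCER"}), True),
        (["DS-CANCER(CC)"], dict(purpose_domain="health", disease_terms={"CANCER"}), True),
        (["DS-CANCER(CC)"], dict(purpose_domain="health", disease_terms={"HIV"}), False),
        (["DS-CANCER(CC)"], dict(purpose_domain="health"), False),
        (["POA"], dict(purpose_domain="poa"), True),
        (["POA"], dict(purpose_domain="health"), False),
        (["GRU(CC)", "TDS-STATINS"], dict(purpose_domain="health", therapy_terms={"STATINS"}), True),
        (["GRU(CC)", "TDS-STATINS"], dict(purpose_domain="health"), False),
        (["HMB(CC)", "RS-PEDIATRIC"], dict(purpose_domain="health", research_type_terms={"PEDIATRIC"}), True),
        (["HMB(CC)", "RS-PEDIATRIC"], dict(purpose_domain="health", research_type_terms={"AGING"}), False),
        (["HMB(CC)", "GSO"], dict(purpose_domain="health", uses_only_nongenetic_data=True), False),
        (["HMB(CC)", "NMDS"], dict(purpose_domain="health", methods_dev="general"), False),
        (["HMB(CC)", "NMDS"], dict(purpose_domain="health", methods_dev="within_bounds"), True),
    ],
)
def test_purpose_regions(tokens, request_kw, permitted):
    p = prof(*tokens)
    ok, reasons, trace = purpose_permitted(
        p.primary, p.secondaries, req(**request_kw), TermMatcher()
    )
    assert ok is permitted, reasons
    assert bool(reasons) != permitted
    assert len(trace) >= 1


def test_general_methods_default_policy():
    # without NMDS, general methods development is inside GRU but outside HMB
    r = req(purpose_domain="health", methods_dev="general")
    assert evaluate(prof("GRU(CC)"), r).status == "PERMIT"
    assert evaluate(prof("HMB(CC)"), r).status == "DENY"
    cfg = EngineConfig(general_methods_primaries=("NRES", "GRU", "HMB"))
    assert evaluate(prof("HMB(CC)"), r, config=cfg).status == "PERMIT"


def test_matcher_required_for_parameterized_codes():
    p = prof("DS-CANCER(CC)")
    with pytest.raises(MatcherRequiredError):
        purpose_permitted(p.primary, p.secondaries, req(), None)


def test_hierarchy_matching_subsumption():
    m = TermMatcher({"breast cancer": "cancer", "cancer": "disease"})
    p = prof("DS-CANCER(CC)")
    r = req(purpose_domain="health", disease_terms={"Breast Cancer"})
    assert evaluate(p, r, term_matcher=m).status == "PERMIT"
    assert evaluate(p, r).status == "DENY"  # exact matcher: no subsumption
    # NDS exclusion also follows the hierarchy downward
    p2 = prof("GRU(CC)", "NDS-CANCER")
    assert evaluate(p2, r, term_matcher=m).status == "DENY"


def test_hpoa_on_ds_requires_disease_match_by_default():
    p = prof("DS-CANCER(CC)", "HPOA")
    r = req(purpose_domain="poa", poa_health_related=True, disease_terms={"HIV"})
    assert evaluate(p, r).status == "DENY"
    relaxed = EngineConfig(hpoa_requires_disease_match=False)
    assert evaluate(p, r, config=relaxed).status == "PERMIT"


# ------------------------------------------------------------------- gates
def test_gate_examples():
    fails, _ = evaluate_gates(
        prof("GRU(CC)", "NPU").requirements,
        req(requester=RequesterAttributes(org_type="for_profit")),
    )
    assert [c for _, c, _ in fails] == ["NPU"]

    fails, _ = evaluate_gates(
        prof("GRU(CC)", "TS-12").requirements, req(duration_months=6)
    )
    assert fails == []

    fails, _ = evaluate_gates(
        prof("GRU(CC)", "GS-EU").requirements,
        req(requester=RequesterAttributes(geography="FR")),
    )
    assert fails == []
    fails, _ = evaluate_gates(
        prof("GRU(CC)", "GS-EU").requirements,
        req(requester=RequesterAttributes(geography="US")),
    )
    assert [c for _, c, _ in fails] == ["GS"]

    fails, _ = evaluate_gates(
        prof("GRU(CC)", "NCU").requirements,
        req(requester=RequesterAttributes(commercial_purpose=True)),
    )
    assert [c for _, c, _ in fails] == ["NCU"]


def test_ts_gate_fails_closed_without_duration_and_rejects_bad_parameter():
    fails, _ = evaluate_gates(prof("GRU(CC)", "TS-12").requirements, req())
    assert [c for _, c, _ in fails] == ["TS"]
    with pytest.raises(ParameterArityError):
        evaluate_gates(prof("GRU(CC)", "TS-soon").requirements, req(duration_months=1))


def test_named_approval_gates():
    p = prof("GRU(CC)", "US", approved_entities={"users": ["alice"]})
    ok = req(requester=RequesterAttributes(user_id="alice"))
    bad = req(requester=RequesterAttributes(user_id="bob"))
    assert evaluate(p, ok).status == "PERMIT"
    assert evaluate(p, bad).status == "DENY"
    # no approved list at all ⇒ requires named approval ⇒ fail
    p2 = prof("GRU(CC)", "US")
    d = evaluate(p2, ok)
    assert d.status == "DENY" and "named approval" in d.denial_reasons[0][2]


# ------------------------------------------------------- obligations & CC
def test_obligations_attested_and_refused():
    p = prof("HMB(CC)", "PUB", "IRB")
    r = req(purpose_domain="health", attestations={"PUB": True, "IRB": True})
    d = evaluate(p, r)
    assert d.status == "PERMIT_WITH_OBLIGATIONS"
    assert [c for c, _ in d.obligations] == ["PUB", "IRB"]

    d = evaluate(p, req(purpose_domain="health", attestations={"PUB": True}))
    assert d.status == "DENY"
    # actionable: the reason names exactly the missing attestation
    assert [(r_, c) for r_, c, _ in d.denial_reasons] == [("OBLIGATION_UNATTESTED", "IRB")]


def test_moratorium_cross_checks_planned_publication_date():
    p = prof("HMB(CC)", "MOR-2030-01-01")
    early = RequesterAttributes(planned_publication_date=datetime.date(2028, 1, 1))
    late = RequesterAttributes(planned_publication_date=datetime.date(2031, 1, 1))
    base = dict(purpose_domain="health", attestations={"MOR": True})
    assert evaluate(p, req(requester=early, **base)).status == "DENY"
    assert evaluate(p, req(requester=late, **base)).status == "PERMIT_WITH_OBLIGATIONS"
    # no planned date given: the attestation alone carries the obligation
    assert evaluate(p, req(**base)).status == "PERMIT_WITH_OBLIGATIONS"


def test_clinical_reference_use_needs_effective_cc():
    r = req(purpose_domain="health", clinical_reference_use=True)
    assert evaluate(prof("HMB(CC)"), r).status == "PERMIT"
    assert evaluate(prof("HMB"), r).status == "DENY"
    d = evaluate(prof("HMB", "RUO"), r)
    assert d.status == "DENY" and d.denial_reasons[0][1] == "RUO"
    # RUO prevails even over a granted (CC) flag
    assert evaluate(prof("HMB(CC)", "RUO"), r).status == "DENY"
    assert evaluate(prof("NRES"), r).status == "PERMIT"


# -------------------------------------------------------------- permissions
def test_biospecimen_intents_gated_by_permission_codes():
    p = prof("DS-ALS(CC)", "GEN", resource_kind=("biospecimen",))
    r = req(
        purpose_domain="health",
        disease_terms={"ALS"},
        biospecimen_intents={"derive_cell_lines"},
    )
    d = evaluate(p, r)
    assert d.status == "DENY" and d.denial_reasons[0][1] == "CL"
    ok = req(
        purpose_domain="health",
        disease_terms={"ALS"},
        biospecimen_intents={"extract_nucleic_acids"},
    )
    d = evaluate(p, ok)
    assert d.status == "PERMIT" and d.granted_permissions == ("GEN",)


def test_granted_permissions_listed():
    p = prof("GRU(CC)", "CQ", "CR", "HR")
    d = evaluate(p, req(purpose_domain="health"))
    assert d.granted_permissions == ("CQ", "CR", "HR")


# ------------------------------------------------------------------- trace
def test_nres_single_line_trace():
    d = evaluate(prof("NRES"), req(purpose_domain="poa"))
    assert d.status == "PERMIT" and len(d.trace) == 1
    assert explain(d).count("\n") == 1


def test_explain_renders_every_denial_reason():
    p = prof("DS-CANCER(CC)", "NPU", "PUB")
    r = req(
        purpose_domain="health",
        disease_terms={"HIV"},
        requester=RequesterAttributes(org_type="for_profit"),
    )
    d = evaluate(p, r)
    text = explain(d)
    assert d.status == "DENY"
    for rule, code, _ in d.denial_reasons:
        assert rule in text and code in text
    assert len(d.trace) == len([ln for ln in text.splitlines() if ln.startswith("  ")])


def test_decisions_are_deterministic():
    p = prof("DS-CANCER(CC)", "NDS-HIV", "PUB", "GS-EU")
    r = req(
        purpose_domain="health",
        disease_terms={"CANCER"},
        attestations={"PUB": True},
        requester=RequesterAttributes(geography="DE"),
    )
    assert evaluate(p, r) == evaluate(p, r)
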
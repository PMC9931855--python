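"""Token grammar, canonical rendering, and profile validation rules."""

import pytest
from hypothesis import given, settings, strategies as st

from consentcodes import (
    CodeInstance,
    get_registry,
    parse_code_token,
    parse_profile,
    render_code_token,
    validate_profile,
)
from consentcodes.errors import (
    CCNotAllowedError,
    ParameterArityError,
    ProfileValidationError,
    TokenSyntaxError,
    UnknownCodeError,
)
from consentcodes.fixtures import PLACEHOLDER_PARAMS


@pytest.mark.parametrize(
    "token,code,param,cc",
    [
        ("DS-CANCER(CC)", "DS", "CANCER", True),
        ("TS-24", "TS", "24", False),
        ("NRES", "NRES", None, False),
        ("  hmb(cc) ", "HMB", None, True),
        ("ds-Breast Cancer", "DS", "Breast Cancer", False),
        ("MOR-2027-01-01", "MOR", "2027-01-01", False),
    ],
)
def test_parse_token(token, code, param, cc):
    inst = parse_code_token(token)
    assert (inst.code, inst.parameter, inst.cc) == (code, param, cc)


@pytest.mark.parametrize(
    "token,exc",
    [
        ("PUB-XX", ParameterArityError),  # PUB takes no parameter
        ("DS", ParameterArityError),      # DS requires one
        ("NPU(CC)", CCNotAllowedError),
        ("XYZ", UnknownCodeError),
        ("", TokenSyntaxError),
        ("DS-", TokenSyntaxError),
        ("DS-(CANCER)", TokenSyntaxError),
        ("123-X", TokenSyntaxError),
    ],
)
def test_parse_token_errors(token, exc):
    with pytest.raises(exc):
        parse_code_token(token)


def test_render_examples():
    assert render_code_token(parse_code_token("DS-CANCER(CC)")) == "DS-CANCER(CC)"
    assert render_code_token(parse_code_token("NRES")) == "NRES"


def test_round_trip_over_registry_with_placeholders():
    for d in get_registry():
        param = PLACEHOLDER_PARAMS.get(d.parameter_role)
        ccs = (False, True) if d.cc_suffix_allowed else (False,)
        for cc in ccs:
            tok = render_code_token(CodeInstance(d, param, cc))
            assert render_code_token(parse_code_token(tok)) == tok


@settings(derandomize=True, max_examples=200)
@given(
    base=st.sampled_from(["DS", "RS", "NDS", "TDS", "GS", "COL", "ARA", "ROR"]),
    param=st.text(
        alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd"), whitelist_characters=" -"),
        min_size=1,
        max_size=20,
    ).filter(lambda s: s.strip() == s and s.strip("-") and " " * 2 not in s),
    cc=st.booleans(),
)
def test_round_trip_is_identity_on_canonical_spellings(base, param, cc):
    cc = cc and get_registry().get(base).cc_suffix_allowed
    tok = f"{base}-{param}" + ("(CC)" if cc else "")
    assert render_code_token(parse_code_token(tok)) == tok


def test_parameter_compared_case_insensitively():
    assert parse_code_token("DS-Cancer") == parse_code_token("DS-CANCER")
    assert parse_code_token("DS-Cancer") != parse_code_token("DS-CANCER(CC)")


def test_parse_profile_valid():
    p = parse_profile(["HMB(CC)", "HPOA", "PUB"], ["data"], is_genetic_resource=True)
    assert p.tokens == ["HMB(CC)", "HPOA", "PUB"]
    # every accepted profile re-validates cleanly
    assert validate_profile(p).valid


def test_two_primaries_rejected():
    with pytest.raises(ProfileValidationError) as e:
        parse_profile(["GRU(CC)", "HMB(CC)"])
    assert e.value.report.violations[0].rule_id == "SINGLE_PRIMARY"


def test_nres_admits_no_companions():
    with pytest.raises(ProfileValidationError) as e:
        parse_profile(["NRES", "PUB"])
    assert any(v.rule_id == "NRES_COMPANIONS" for v in e.value.report.errors)
    # overridable reading
    p = parse_profile(["NRES", "PUB"], allow_nres_companions=True)
    assert p.has("PUB")


def test_hpoa_scope():
    with pytest.raises(ProfileValidationError) as e:
        parse_profile(["GRU(CC)", "HPOA"])
    assert any(v.rule_id == "HPOA_SCOPE" for v in e.value.report.errors)


def test_self_contradiction_ds_nds():
    with pytest.raises(ProfileValidationError) as e:
        parse_profile(["DS-HIV(CC)", "NDS-HIV"])
    assert any(v.rule_id == "SELF_CONTRADICTION" for v in e.value.report.errors)
    # different diseases are fine: several NDS exclusions may coexist
    p = parse_profile(["DS-HIV(CC)", "NDS-TB", "NDS-MALARIA"])
    assert len(p.instances_of("NDS")) == 2


def test_cc_ruo_redundancy_is_a_warning():
    p = parse_profile(["HMB(CC)", "RUO"])
    report = validate_profile(p)
    assert report.valid
    assert any(v.rule_id == "CC_RUO_REDUNDANT" for v in report.warnings)


def test_gso_scope():
    with pytest.raises(ProfileValidationError) as e:
        parse_profile(["HMB(CC)", "GSO"], is_genetic_resource=False)
    assert any(v.rule_id == "GSO_SCOPE" for v in e.value.report.errors)
    parse_profile(["HMB(CC)", "GSO"], is_genetic_resource=True)


def test_biospecimen_codes_need_biospecimen_resource():
    with pytest.raises(ProfileValidationError) as e:
        parse_profile(["HMB(CC)", "CL"], ["data"])
    assert any(v.rule_id == "BIOSPECIMEN_SCOPE" for v in e.value.report.errors)
    parse_profile(["HMB(CC)", "CL"], ["data", "biospecimen"])


def test_npu_and_ncu_coexist():
    # they constrain different axes: organization type vs use type
    p = parse_profile(["GRU(CC)", "NPU", "NCU"])
    assert p.has("NPU") and p.has("NCU")


def test_unknown_codes_permissive_mode():
    with pytest.raises(UnknownCodeError):
        parse_profile(["HMB(CC)", "ZZTOP"])
    p = parse_profile(["HMB(CC)", "ZZTOP"], permissive=True)
    assert p.unknown_tokens == ("ZZTOP",)
    assert any(v.rule_id == "UNKNOWN_CODE" for v in validate_profile(p).warnings)


def test_validation_is_pure(profile_grid_1_1):
    for p in profile_grid_1_1[:50]:
        assert validate_profile(p) == validate_profile(p)
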
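"""Catalog reading/writing and request-driven filtering."""

import json

import pytest

from consentcodes import (
    AccessRequest,
    filter_catalog,
    read_catalog,
    summarize_decisions,
    write_catalog,
    write_decisions,
)
from consentcodes.catalog import read_decisions
from consentcodes.errors import CatalogError
from consentcodes.fixtures import emit, random_request

CATALOG = {
    "datasets": [
        {
            "dataset_id": "D1",
            "title": "broad consent cohort",
            "resource_kind": ["data"],
            "is_genetic_resource": True,
            "profile_tokens": ["GRU(CC)"],
        },
        {
            "dataset_id": "D2",
            "title": "biomedical cohort",
            "resource_kind": ["data"],
            "is_genetic_resource": True,
            "profile_tokens": ["HMB(CC)", "PUB"],
        },
        {
            "dataset_id": "D3",
            "title": "ancestry panel",
            "resource_kind": ["data"],
            "is_genetic_resource": True,
            "profile_tokens": ["POA"],
        },
    ]
}


@pytest.fixture
def catalog_path(tmp_path):
    p = tmp_path / "catalog.json"
    p.write_text(json.dumps(CATALOG))
    return p


def test_read_catalog_json(catalog_path):
    entries = read_catalog(catalog_path)
    assert [e.dataset_id for e in entries] == ["D1", "D2", "D3"]
    assert entries[1].profile.tokens == ["HMB(CC)", "PUB"]


def test_read_empty_catalog(tmp_path):
    p = tmp_path / "empty.json"
    p.write_text('{"datasets": []}')
    assert read_catalog(p) == []


def test_invalid_entry_strict_vs_lenient(tmp_path):
    bad = {
        "datasets": CATALOG["datasets"]
        + [
            {
                "dataset_id": "D4",
                "resource_kind": ["data"],
                "profile_tokens": ["GRU(CC)", "HPOA"],  # HPOA needs HMB/DS
            }
        ]
    }
    p = tmp_path / "bad.json"
    p.write_text(json.dumps(bad))
    with pytest.raises(CatalogError, match="D4"):
        read_catalog(p)
    entries = read_catalog(p, strict=False)
    assert [e.dataset_id for e in entries] == ["D1", "D2", "D3"]


def test_read_catalog_tsv(tmp_path):
    p = tmp_path / "catalog.tsv"
    p.write_text(
        "dataset_id\ttitle\tresource_kind\tis_genetic_resource\tprofile_tokens\tapproved_users\n"
        "T1\tone\tdata\ttrue\tGRU(CC)\t\n"
        "T2\ttwo\tdata,biospecimen\tfalse\tHMB(CC),PUB,CL\talice,bob\n"
    )
    entries = read_catalog(p)
    assert entries[1].profile.tokens == ["HMB(CC)", "PUB", "CL"]
    assert entries[1].profile.approved_entities == {"users": ["alice", "bob"]}


def test_filter_catalog_poa_request(catalog_path):
    entries = read_catalog(catalog_path)
    request = AccessRequest(purpose_domain="poa")
    decisions = filter_catalog(entries, request)
    assert [d.status for d in decisions.values()] == ["PERMIT", "DENY", "PERMIT"]
    assert summarize_decisions(decisions) == {
        "PERMIT": 2, "PERMIT_WITH_OBLIGATIONS": 0, "DENY": 1,
    }


def test_filter_output_invariant_to_entry_order(catalog_path):
    entries = read_catalog(catalog_path)
    request = random_request(3)
    fwd = filter_catalog(entries, request)
    rev = filter_catalog(list(reversed(entries)), request)
    assert list(fwd) == list(rev) and fwd == rev


def test_catalog_write_read_round_trip(tmp_path, catalog_path):
    entries = read_catalog(catalog_path)
    out = tmp_path / "rt.json"
    write_catalog(entries, out)
    again = read_catalog(out)
    assert [(e.dataset_id, e.profile.tokens) for e in entries] == [
        (e.dataset_id, e.profile.tokens) for e in again
    ]


@pytest.mark.parametrize("fmt", ["json", "tsv"])
def test_decisions_round_trip(tmp_path, catalog_path, fmt):
    decisions = filter_catalog(
        read_catalog(catalog_path),
        AccessRequest(purpose_domain="health", attestations={"PUB": True}),
    )
    out = tmp_path / f"decisions.{fmt}"
    write_decisions(decisions, out, fmt)
    back = read_decisions(out)
    assert {k: v["status"] for k, v in back.items()} == {
        k: d.status for k, d in decisions.items()
    }


def test_empty_decisions_tsv_has_header_only(tmp_path):
    out = tmp_path / "empty.tsv"
    write_decisions({}, out, "tsv")
    assert out.read_text().strip() == "dataset_id\tstatus\tobligations\tdenial_reasons"


def test_emitted_fixture_catalogs_are_readable(tmp_path):
    payload = emit(seed=11, n_profiles=5, n_requests=2)
    p = tmp_path / "emitted.json"
    p.write_text(json.dumps(payload["catalog"]))
    entries = read_catalog(p)
    assert len(entries) == 5
    for rd in payload["requests"]:
        AccessRequest.from_dict(rd)
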
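"""Dataset catalogs tagged with consent profiles.

Canonical exchange format is JSON::

    {"datasets": [
        {"dataset_id": "EGAD1", "title": "...",
         "resource_kind": ["data"], "is_genetic_resource": true,
         "profile_tokens": ["HMB(CC)", "PUB", "IRB"],
         "approved_entities": {"users": [...], ...}},
        ...
    ]}

A TSV dialect is supported for spreadsheet-based curation: UTF-8,
tab-delimited, header row, ``resource_kind`` and ``profile_tokens`` as
comma-separated strings and approved entities in ``approved_users`` /
``approved_projects`` / ``approved_institutions`` columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .engine import AccessRequest, Decision, EngineConfig, DEFAULT_CONFIG, evaluate
from .errors import CatalogError, ConsentCodeError
from .parser import ConsentProfile, parse_profile
from .terms import RegionTable, TermMatcher

__all__ = [
    "CatalogEntry",
    "read_catalog",
    "write_catalog",
    "filter_catalog",
    "summarize_decisions",
    "write_decisions",
    "read_decisions",
]

log = logging.getLogger("consentcodes.catalog")


@dataclass(frozen=True)
class CatalogEntry:
    dataset_id: str
    title: str
    profile: ConsentProfile

    @property
    def profile_tokens(self) -> list[str]:
        return self.profile.tokens


def _entry_from_record(rec: Mapping, permissive: bool = False) -> CatalogEntry:
    did = rec.get("dataset_id")
    if not did:
        raise CatalogError("catalog entry without dataset_id")
    tokens = rec.get("profile_tokens") or rec.get("codes")
    if not tokens:
        raise CatalogError(f"{did}: no consent-code tokens", dataset_id=did)
    if isinstance(tokens, str):
        tokens = [t.strip() for t in tokens.split(",") if t.strip()]
    try:
        profile = parse_profile(
            tokens,
            resource_kind=rec.get("resource_kind", ("data",)),
            is_genetic_resource=bool(rec.get("is_genetic_resource", False)),
            approved_entities=rec.get("approved_entities"),
            permissive=permissive,
        )
    except ConsentCodeError as e:
        raise CatalogError(f"{did}: {e}", dataset_id=did) from e
    return CatalogEntry(
        dataset_id=str(did), title=str(rec.get("title", "")), profile=profile
    )


def _records_from_tsv(path: Path) -> list[dict]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for rec in df.to_dict(orient="records"):
        approved = {}
        for key, col in (
            ("users", "approved_users"),
            ("projects", "approved_projects"),
            ("institutions", "approved_institutions"),
        ):
            vals = [v.strip() for v in (rec.get(col) or "").split(",") if v.strip()]
            if vals:
                approved[key] = vals
        records.append(
            {
                "dataset_id": rec.get("dataset_id"),
                "title": rec.get("title", ""),
                "resource_kind": [
                    k.strip()
                    for k in (rec.get("resource_kind") or "data").split(",")
                    if k.strip()
                ],
                "is_genetic_resource": (rec.get("is_genetic_resource") or "")
                .strip()
                .lower()
                in ("true", "1", "yes"),
                "profile_tokens": rec.get("profile_tokens"),
                "approved_entities": approved or None,
            }
        )
    return records


def read_catalog(
    path: str | Path, *, strict: bool = True, permissive_codes: bool = False
) -> list[CatalogEntry]:
    """Read and profile-validate a JSON or TSV catalog.

    Strict mode aborts on the first invalid entry; lenient mode skips
    invalid entries with a logged warning. ``permissive_codes`` forwards the
    unknown-code-tolerant parsing mode.
    """
    path = Path(path)
    if not path.exists():
        raise CatalogError(f"catalog file {path} does not exist")
    if path.suffix.lower() in (".tsv", ".txt"):
        records = _records_from_tsv(path)
    else:
        try:
            payload = json.loads(path.read_text("utf-8") or "null")
        except json.JSONDecodeError as e:
            raise CatalogError(f"{path}: not valid JSON ({e})") from e
        if payload is None:
            records = []
        elif isinstance(payload, list):
            records = payload
        elif isinstance(payload, dict) and isinstance(payload.get("datasets"), list):
            records = payload["datasets"]
        else:
            raise CatalogError(f'{path}: expected a list or {{"datasets": [...]}}')
    entries: list[CatalogEntry] = []
    seen: set[str] = set()
    for rec in records:
        try:
            entry = _entry_from_record(rec, permissive=permissive_codes)
            if entry.dataset_id in seen:
                raise CatalogError(
                    f"duplicate dataset_id {entry.dataset_id}",
                    dataset_id=entry.dataset_id,
                )
            seen.add(entry.dataset_id)
            entries.append(entry)
        except CatalogError as e:
            if strict:
                raise
            log.warning("skipping invalid catalog entry: %s", e)
    return entries


def write_catalog(entries: list[CatalogEntry], path: str | Path) -> None:
    """Write entries back out as canonical JSON."""
    payload = {
        "datasets": [
            {
                "dataset_id": e.dataset_id,
                "title": e.title,
                "resource_kind": sorted(e.profile.resource_kind),
                "is_genetic_resource": e.profile.is_genetic_resource,
                "profile_tokens": e.profile.tokens,
                "approved_entities": (
                    {k: list(v) for k, v in e.profile.approved_entities.items()}
                    if e.profile.approved_entities
                    else None
                ),
            }
            for e in entries
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", "utf-8")


def filter_catalog(
    catalog: list[CatalogEntry],
    request: AccessRequest,
    term_matcher: TermMatcher | None = None,
    region_table: RegionTable | None = None,
    config: EngineConfig = DEFAULT_CONFIG,
) -> dict[str, Decision]:
    """One decision per entry, keyed and ordered by dataset_id.

    Output is invariant to the input order of the catalog.
    """
    return {
        e.dataset_id: evaluate(e.profile, request, term_matcher, region_table, config)
        for e in sorted(catalog, key=lambda e: e.dataset_id)
    }


def summarize_decisions(decisions: Mapping[str, Decision]) -> dict[str, int]:
    counts = {"PERMIT": 0, "PERMIT_WITH_OBLIGATIONS": 0, "DENY": 0}
    for d in decisions.values():
        counts[d.status] += 1
    return counts


def _obligation_token(code: str, param: str | None) -> str:
    return code if param is None else f"{code}-{param}"


def write_decisions(
    decisions: Mapping[str, Decision], path: str | Path, fmt: str | None = None
) -> None:
    """Write decisions as JSON (full detail) or TSV (stable flat columns:
    dataset_id, status, obligations, denial_reasons)."""
    path = Path(path)
    if fmt is None:
        fmt = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "json"
    ids = sorted(decisions)
    if fmt == "json":
        payload = {i: decisions[i].to_dict() for i in ids}
        path.write_text(json.dumps(payload, indent=2) + "\n", "utf-8")
    elif fmt == "tsv":
        df = pd.DataFrame(
            [
                {
                    "dataset_id": i,
                    "status": decisions[i].status,
                    "obligations": ";".join(
                        _obligation_token(c, p) for c, p in decisions[i].obligations
                    ),
                    "denial_reasons": ";".join(
                        f"{rule}:{code}"
                        for rule, code, _ in decisions[i].denial_reasons
                    ),
                }
                for i in ids
            ],
            columns=["dataset_id", "status", "obligations", "denial_reasons"],
        )
        df.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown decisions format {fmt!r}")


def read_decisions(path: str | Path) -> dict[str, dict]:
    """Read decisions back (both formats) as plain dicts keyed by dataset_id."""
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        return {
            r["dataset_id"]: {
                "status": r["status"],
                "obligations": [t for t in r["obligations"].split(";") if t],
                "denial_reasons": [t for t in r["denial_reasons"].split(";") if t],
            }
            for r in df.to_dict(orient="records")
        }
    return json.loads(path.read_text("utf-8"))
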
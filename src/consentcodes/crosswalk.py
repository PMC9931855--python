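"""Crosswalks to GA4GH DUO terms and HL7 Purpose-of-Use codes.

Two fidelity-annotated mapping tables ship with the package:

* ``duo_crosswalk.tsv`` — the Consent Code ↔ DUO correspondence against the
  DUO 2021-02-23 release, including the codes with no DUO term and the
  cautionary notes (the DUO GRU term DUO:0000042 is much broader than
  GRU(CC); the DUO NMDS term DUO:0000015 prohibits all methods development;
  the DUO NCU term DUO:0000046 defines non-commercial differently);
* ``hl7_pou.tsv`` — the HL7 Healthcare Privacy and Security Classification
  System Research Purpose-of-Use codes with their stated Consent Code
  equivalences (BIOHRCH ↔ HMB(CC), DSHRCH ↔ DS-[XX](CC), POAHRCH ↔ HPOA)
  and the looser DISHRCH ~ {RS, TDS, GSO} relation. The clinical-trial
  codes (CLINTRCH, CLINTRCHNPC, CLINTRCHPC, PRECLINTRCH) and TRANSHRCH
  have no Consent Code counterpart. GRU(CC) → HRESCH is this package's own
  interpretation (fidelity ``broader``, with a caution), not a stated
  equivalence.

Fidelity values: ``exact``, ``broader``, ``narrower``, ``related``; and
``none`` for unmapped codes or target-only entries.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import pandas as pd

from .errors import CrosswalkError
from .parser import CodeInstance, parse_code_token
from .registry import get_registry

__all__ = [
    "DUO_SNAPSHOT",
    "CrosswalkEntry",
    "to_duo",
    "from_duo",
    "to_hl7_purpose_of_use",
    "coverage_report",
]

#: the DUO release the packaged correspondence table was transcribed against
DUO_SNAPSHOT = "2021-02-23"

_DUO_RE = re.compile(r"^DUO:\d{7}$")

FIDELITIES = ("exact", "broader", "narrower", "related", "none")


@dataclass(frozen=True)
class CrosswalkEntry:
    consent_code: str | None
    target_system: str  # "DUO" | "HL7_POU"
    target_id: str | None
    fidelity: str
    caution: str | None = None
    parameter: str | None = None  # carried through from the code instance

    def __post_init__(self):
        if self.consent_code is None and self.target_id is None:
            raise ValueError("entry needs a consent code or a target id")
        if self.fidelity not in FIDELITIES:
            raise ValueError(f"bad fidelity {self.fidelity!r}")


def _read_tsv(name: str) -> list[dict]:
    text = (
        resources.files("consentcodes.data").joinpath(name).read_text("utf-8")
    )
    return list(csv.DictReader(text.splitlines(), delimiter="\t"))


@lru_cache(maxsize=1)
def _duo_rows() -> list[dict]:
    return _read_tsv("duo_crosswalk.tsv")


@lru_cache(maxsize=1)
def _hl7_rows() -> list[dict]:
    return _read_tsv("hl7_pou.tsv")


def _coerce(instance_or_code: CodeInstance | str) -> CodeInstance:
    if isinstance(instance_or_code, CodeInstance):
        return instance_or_code
    return parse_code_token(instance_or_code)


def to_duo(code: CodeInstance | str) -> CrosswalkEntry:
    """DUO entry for one code instance; ``fidelity="none"`` when unmapped."""
    inst = _coerce(code)
    for row in _duo_rows():
        if row["consent_code"] == inst.code:
            return CrosswalkEntry(
                consent_code=inst.code,
                target_system="DUO",
                target_id=row["target_id"] or None,
                fidelity=row["fidelity"],
                caution=row.get("caution") or None,
                parameter=inst.parameter,
            )
    raise CrosswalkError(f"no DUO crosswalk row for {inst.code}")


def from_duo(duo_id: str) -> CrosswalkEntry:
    """Inverse lookup of :func:`to_duo` on the mapped subset.

    Known target-only accessions (e.g. DUO:0000042) return an entry with
    ``consent_code=None`` and their caution; unknown but well-formed
    accessions return a bare target-only entry.
    """
    duo_id = duo_id.strip()
    if not _DUO_RE.match(duo_id):
        raise CrosswalkError(
            f"malformed DUO accession {duo_id!r} (expected DUO:NNNNNNN)"
        )
    for row in _duo_rows():
        if row["target_id"] == duo_id:
            return CrosswalkEntry(
                consent_code=row["consent_code"] or None,
                target_system="DUO",
                target_id=duo_id,
                fidelity=row["fidelity"] if row["consent_code"] else "none",
                caution=row.get("caution") or None,
            )
    return CrosswalkEntry(
        consent_code=None,
        target_system="DUO",
        target_id=duo_id,
        fidelity="none",
        caution="no corresponding Consent Code in the packaged table",
    )


def to_hl7_purpose_of_use(code: CodeInstance | str) -> list[CrosswalkEntry]:
    """HL7 Purpose-of-Use entries for one code instance.

    Stated equivalences come back with ``fidelity="exact"``; RS/TDS/GSO map
    to DISHRCH as ``related``; GRU maps to HRESCH as ``broader`` (package
    interpretation); every other code returns a single unmapped entry.
    """
    inst = _coerce(code)
    get_registry().get(inst.code)  # raises UnknownCodeError for bad ids
    out = [
        CrosswalkEntry(
            consent_code=inst.code,
            target_system="HL7_POU",
            target_id=row["target_id"],
            fidelity=row["fidelity"],
            caution=row.get("caution") or None,
            parameter=inst.parameter,
        )
        for row in _hl7_rows()
        if row["consent_code"] == inst.code
    ]
    if not out:
        out = [
            CrosswalkEntry(
                consent_code=inst.code,
                target_system="HL7_POU",
                target_id=None,
                fidelity="none",
                parameter=inst.parameter,
            )
        ]
    return out


def coverage_report() -> pd.DataFrame:
    """One row per consent code (DUO + HL7 status) and per target-only
    DUO/HL7 identifier; counts conserve against the registry."""
    registry = get_registry()
    duo_by_code = {r["consent_code"]: r for r in _duo_rows() if r["consent_code"]}
    hl7_by_code: dict[str, list[dict]] = {}
    for r in _hl7_rows():
        if r["consent_code"]:
            hl7_by_code.setdefault(r["consent_code"], []).append(r)

    rows = []
    for d in registry:
        duo = duo_by_code.get(d.id, {})
        hl7 = hl7_by_code.get(d.id, [])
        rows.append(
            {
                "kind": "consent_code",
                "consent_code": d.id,
                "tier": d.tier.value,
                "duo_id": duo.get("target_id") or None,
                "duo_fidelity": duo.get("fidelity", "none"),
                "hl7_ids": ";".join(r["target_id"] for r in hl7) or None,
                "hl7_fidelity": ";".join(r["fidelity"] for r in hl7) or "none",
            }
        )
    for r in _duo_rows():
        if not r["consent_code"]:
            rows.append(
                {
                    "kind": "duo_target_only",
                    "consent_code": None,
                    "tier": None,
                    "duo_id": r["target_id"],
                    "duo_fidelity": "none",
                    "hl7_ids": None,
                    "hl7_fidelity": None,
                }
            )
    seen_hl7 = set()
    for r in _hl7_rows():
        if not r["consent_code"] and r["target_id"] not in seen_hl7:
            seen_hl7.add(r["target_id"])
            rows.append(
                {
                    "kind": "hl7_target_only",
                    "consent_code": None,
                    "tier": None,
                    "duo_id": None,
                    "duo_fidelity": None,
                    "hl7_ids": r["target_id"],
                    "hl7_fidelity": "none",
                }
            )
    return pd.DataFrame(rows)
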
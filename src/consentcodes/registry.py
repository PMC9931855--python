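"""The Consent Codes v4 code registry.

The registry is the authoritative in-package transcription of the published
v4 code table (15 July 2020): five primary data/biospecimen use categories
(of which a profile picks exactly one), seven secondary modifier categories,
and the requirement and permission codes. It ships as a packaged TSV so a
curator can audit it without reading Python; it is loaded once and frozen.

Tiers
-----
PRIMARY
    The base permission region: NRES, GRU, HMB, DS-[XX], POA.
SECONDARY
    Conjunctive modifiers of the primary region: TDS, RS, NDS, HPOA, NMDS,
    RUO, GSO.
REQUIREMENT
    Conditions of use — fact gates (NPU, NCU, GS, TS, US, PS, IS) and
    attestation obligations (BEN, PUB, COL, ROR, RTN, IRB, MOR, OS).
PERMISSION
    Grants attached to the resource: recontact codes (CQ, CS, CR), medical
    record access (HR), associated resources (ARA), and the biospecimen
    permissions GEN (nucleic-acid extraction) and CL (cell-line derivation).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterator

from .errors import UnknownCodeError

__all__ = [
    "Tier",
    "ParameterRole",
    "CodeDefinition",
    "Registry",
    "get_registry",
    "get_definition",
    "list_codes",
]


class Tier(str, enum.Enum):
    PRIMARY = "PRIMARY"
    SECONDARY = "SECONDARY"
    REQUIREMENT = "REQUIREMENT"
    PERMISSION = "PERMISSION"


class ParameterRole(str, enum.Enum):
    """What the ``[XX]`` slot of a parameterized code holds."""

    NONE = "none"
    DISEASE = "disease"
    THERAPY_OR_DRUG = "therapy_or_drug"
    RESEARCH_TYPE = "research_type"
    INVESTIGATORS = "investigators"
    ROR_POLICY = "ror_policy"
    GEOGRAPHIC_REGION = "geographic_region"
    DATE = "date"
    MONTHS = "months"
    REPOSITORY_LINK = "repository_link"


@dataclass(frozen=True)
class CodeDefinition:
    """One row of the v4 code table."""

    id: str
    name: str
    tier: Tier
    parameter_role: ParameterRole
    cc_suffix_allowed: bool
    applies_to: frozenset[str]  # subset of {"data", "biospecimen"}
    genetic_only: bool
    biospecimen_only: bool
    version_introduced: str  # "v1" .. "v4"
    description: str
    row_order: int = field(compare=False, default=0)

    @property
    def parameterized(self) -> bool:
        return self.parameter_role is not ParameterRole.NONE


def _parse_bool(s: str) -> bool:
    return s.strip().lower() == "true"


class Registry:
    """Immutable, ordered collection of :class:`CodeDefinition`.

    Order is the row order of the published table, which :meth:`list_codes`
    preserves.
    """

    def __init__(self, definitions: list[CodeDefinition]):
        self._order = tuple(definitions)
        self._by_id = {d.id: d for d in definitions}
        if len(self._by_id) != len(self._order):
            raise ValueError("duplicate code ids in registry table")

    @classmethod
    def from_tsv(cls, text: str) -> "Registry":
        rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
        defs = []
        for i, row in enumerate(rows):
            defs.append(
                CodeDefinition(
                    id=row["id"],
                    name=row["name"],
                    tier=Tier(row["tier"]),
                    parameter_role=ParameterRole(row["parameter_role"]),
                    cc_suffix_allowed=_parse_bool(row["cc_suffix_allowed"]),
                    applies_to=frozenset(
                        p.strip() for p in row["applies_to"].split(",") if p.strip()
                    ),
                    genetic_only=_parse_bool(row["genetic_only"]),
                    biospecimen_only=_parse_bool(row["biospecimen_only"]),
                    version_introduced=row["version_introduced"],
                    description=row["description"],
                    row_order=i,
                )
            )
        return cls(defs)

    def __iter__(self) -> Iterator[CodeDefinition]:
        return iter(self._order)

    def __len__(self) -> int:
        return len(self._order)

    def __contains__(self, code_id: str) -> bool:
        return code_id in self._by_id

    def get(self, code_id: str) -> CodeDefinition:
        try:
            return self._by_id[code_id]
        except KeyError:
            raise UnknownCodeError(code_id) from None

    def list(
        self,
        tier: Tier | str | None = None,
        *,
        parameterized: bool | None = None,
        cc_suffix_allowed: bool | None = None,
        genetic_only: bool | None = None,
        biospecimen_only: bool | None = None,
        applies_to: str | None = None,
    ) -> list[CodeDefinition]:
        """Codes in table order, optionally filtered by tier and flags."""
        if tier is not None:
            tier = Tier(tier)
        out = []
        for d in self._order:
            if tier is not None and d.tier is not tier:
                continue
            if parameterized is not None and d.parameterized != parameterized:
                continue
            if cc_suffix_allowed is not None and d.cc_suffix_allowed != cc_suffix_allowed:
                continue
            if genetic_only is not None and d.genetic_only != genetic_only:
                continue
            if biospecimen_only is not None and d.biospecimen_only != biospecimen_only:
                continue
            if applies_to is not None and applies_to not in d.applies_to:
                continue
            out.append(d)
        return out


@lru_cache(maxsize=1)
def get_registry() -> Registry:
    """The packaged v4 registry, loaded once per process."""
    text = (
        resources.files("consentcodes.data")
        .joinpath("consent_codes_v4.tsv")
        .read_text(encoding="utf-8")
    )
    return Registry.from_tsv(text)


def get_definition(code_id: str) -> CodeDefinition:
    """Look up one code by its case-sensitive upper-case identifier."""
    return get_registry().get(code_id)


def list_codes(tier: Tier | str | None = None, **flags) -> list[CodeDefinition]:
    """Codes of the packaged registry in table order; see :meth:`Registry.list`."""
    return get_registry().list(tier, **flags)
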
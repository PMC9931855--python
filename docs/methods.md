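# Methods

## The model

Consent Codes are a controlled vocabulary for the consent-based conditions
under which shared research datasets and biospecimen collections may be
re-used. A resource carries a *profile*: exactly one **primary category**
fixing the base region of permitted research purposes, plus optional
**secondary categories** that modify that region conjunctively, plus
**requirement** and **permission** codes that condition or extend use. This
package makes the vocabulary executable: a profile and a structured access
request go in; PERMIT, PERMIT_WITH_OBLIGATIONS or DENY comes out, with a
rule trace.

The purpose semantics are a region map over three research domains —
`other_biological`, `health`, and `poa` (population origins or ancestry):

* **NRES** — open access, no restrictions at all. Modelled as a
  short-circuit: every well-formed request is permitted with no
  obligations, and the profile validator rejects companion codes on NRES
  (the open-access reading; overridable via `allow_nres_companions`).
* **GRU** — health/medical/biomedical purposes *and other biological
  research*, including ancestry research: all three domains.
* **HMB** — health only; ancestry research is outside the region unless
  the profile carries **HPOA** and the request declares its ancestry
  analysis health-related.
* **DS-[XX]** — health research related to the named disease. The request's
  disease terms must *all* fall under the parameter (fail-closed: a study
  spanning the named disease and an unrelated one is not "limited to" the
  disease). HPOA on a DS profile additionally requires the ancestry
  analysis to match the disease (most restrictive reading; configurable
  via `EngineConfig.hpoa_requires_disease_match` because the vocabulary
  itself does not settle the point).
* **POA** — ancestry research only.

Secondary modifiers apply conjunctively: **TDS-[XX]** and **RS-[XX]**
require the request's therapy / research-type terms to fall under their
parameters (same all-terms-match rule as DS); **NDS-[XX]** vetoes any
request whose disease terms match the excluded area; **NMDS** vetoes
`methods_dev="general"` while leaving `within_bounds` development
untouched; **GSO** vetoes requests using only non-genetic data; **RUO**
vetoes clinical reference use even when the primary carries the `(CC)`
flag (most restrictive interpretation — the validator flags the
combination as a warning, `CC_RUO_REDUNDANT`).

When NMDS is absent, general methods development is accepted only under
NRES and GRU. This is a genuine policy gap: the modifier's name points one
way and its description the other. The packaged default follows the region
map, where the general-methods region lies outside HMB/DS/POA; it is
configurable via `EngineConfig.general_methods_primaries`.

Clinical reference use (`(CC)`) permits research data to serve as
background reference data in clinical activities — never an individual's
own care. A request with `clinical_reference_use=True` needs an *effective*
flag: `cc=True` on the primary and no RUO in the profile. NRES needs no
flag.

Requirement codes split into two mechanically different kinds:

* **fact gates**, checked against requester attributes — NPU (organization
  type), NCU (commercial purpose; broader than NPU, and deliberately
  allowed to coexist with it since they constrain different axes), GS-[XX]
  (geography within a region table), TS-[XX] (requested duration ≤ the
  approved months), US/PS/IS (identifier listed among the resource's
  approved users/projects/institutions; a missing list fails closed as
  "requires named approval");
* **attestation obligations** — BEN, PUB, COL-[XX], ROR-[XX], RTN, IRB,
  MOR-[XX], OS. Each present code must be affirmatively attested in the
  request, otherwise DENY with a reason naming exactly the missing
  attestation (fail-closed, and actionable). MOR is an attestation, with
  an extra cross-check: when the profile's embargo date and the
  requester's planned publication date are both known, publishing before
  the embargo denies.

Permission codes never deny on their own; CQ/CS/CR/HR/ARA/GEN/CL present
in a profile are echoed as `granted_permissions`. The two biospecimen
intents are gated: deriving cell lines needs CL, extracting nucleic acids
needs GEN.

Decision status: DENY if any reason accumulated; else
PERMIT_WITH_OBLIGATIONS when attestation obligations exist; else PERMIT.
Every rule firing is recorded in an ordered trace; `explain()` renders it
with each code's registry description. Decisions are pure functions of
their inputs.

## Parameters and matching

Code parameters (`[XX]`) are free text: case-preserved for display,
compared case-insensitively after whitespace collapsing. Term matching
defaults to normalized exact equality; an optional child→parent hierarchy
table (TSV: `term`, `parent`) enables subsumption, so "breast cancer"
satisfies `DS-CANCER` and is also caught by `NDS-CANCER`. Ontology binding
is left to deployments — the vocabulary itself attaches no syntax to the
placeholder.

TS parameters are integer months; MOR parameters are ISO-8601 dates (both
checked: non-conforming values draw a validation warning at parse time,
and TS additionally raises at gate time). GS parameters are resolved
against a region-membership table; the packaged one groups ISO-3166
alpha-2 country codes into EU, EEA, NORTH_AMERICA and AFRICA and can be
replaced wholesale (`RegionTable.from_tsv`). A geography equal to the
region label itself also passes, so deployments can tag requesters with
region names directly.

The registry, DUO crosswalk, HL7 Purpose-of-Use crosswalk and region table
all ship as TSV files inside the package so that a curator can audit them
without reading code; they are loaded once per process and frozen. The
`version_introduced` column records vocabulary provenance for display only
(v1 original set; v2 RTN; v3 TDS, NDS, CQ, CS, CR, HR; v4 HPOA, NCU, BEN,
ROR, OS, ARA, GEN, CL); per-version historical registries are not
reconstructed.

## Crosswalks

The DUO table maps each code to its GA4GH DUO accession (2021-02-23
release) or marks it unmapped, carrying three cautions verbatim: the DUO
GRU term (DUO:0000042) is much broader than GRU(CC); the DUO NMDS term
(DUO:0000015) prohibits all methods development; the DUO NCU term
(DUO:0000046) defines non-commercial use differently. `from_duo` inverts
the mapped subset and returns annotated target-only entries for those
three accessions.

The HL7 table records the stated equivalences — BIOHRCH ↔ HMB(CC),
DSHRCH ↔ DS-[XX](CC), POAHRCH ↔ HPOA — and DISHRCH as *related* to RS,
TDS and GSO (the conditions distinguishing the three are unspecified, so
no inverse is offered for DISHRCH). GRU(CC) → HRESCH is mapped with
fidelity `broader` and a caution: it is this package's interpretation, not
a stated equivalence. The clinical-trial codes (CLINTRCH, CLINTRCHNPC,
CLINTRCHPC, PRECLINTRCH) and TRANSHRCH are target-only.

## Synthetic data and the oracle

`consentcodes.fixtures` generates everything the tests consume:

* **request grid** — the exhaustive enumeration of canonical requests:
  3 purpose domains × 3 term-match levels (match/mismatch/none, applied to
  disease, therapy and research-type terms alike so every parameterized
  modifier is exercised) × 2 ancestry-health flags × 3 methods levels ×
  2 clinical-use flags × 2 non-genetic flags × 3 requester archetypes
  (non-profit, for-profit research, for-profit commercial) × 2 attestation
  archetypes (all-yes, all-no) = 1,296 requests;
* **profile grid** — all valid profiles with bounded companions and
  placeholder parameters ("X"; "12" months; a far-future embargo date),
  both `(CC)` variants of GRU/HMB/DS, built on a genetic data+biospecimen
  resource so every code is admissible. Invalid combinations drop out by
  re-validation;
* **seeded generators** — `random_profile` / `random_request`, pure
  functions of their seed, drawing parameters from a small realistic
  vocabulary;
* **oracle** — `oracle_evaluate`, a deliberately naive straight-line
  re-implementation of the whole semantics, one conditional per code-table
  row, sharing no evaluation logic with the engine (only the frozen data
  tables and the `Decision` container). Engine and oracle are compared on
  `(status, sorted obligations, denial-reason code set, granted
  permissions)`.

The equivalence check pairs every request with the 8 bare primaries and a
stride-7 subsample (186 requests, coprime to every factor cardinality so
all levels stay covered) with the ~1,200 one-secondary/one-requirement
profiles — ≈ 2.3 × 10⁵ pairs, about a minute of work in total across the
suite. Pairwise code interactions beyond one-of-each are covered by the
1,000-pair seeded monotonicity sweep, which attaches every absent
requirement-tier code to random multi-companion profiles.

What the synthetic conditions do *not* model: real-world code frequency
distributions (dbGaP/EGA), free-text messiness in parameters, ontology-
scale disease hierarchies, or adversarial requests. Passing tests show the
engine implements the vocabulary's semantics exactly as specified here;
they do not show that a deployment's term bindings or region tables are
correct for its data.

## Known limitations

* Whether requirement codes may attach to NRES, the default
  general-methods policy without NMDS, and whether HPOA on DS scopes
  ancestry analysis to the named disease are all underdetermined by the
  vocabulary; the package picks the restrictive reading for each and
  exposes a switch (`allow_nres_companions`, `EngineConfig`).
* All-terms-must-match is a deliberate fail-closed choice for DS/TDS/RS;
  a related-to (any-term) reading would admit broader studies.
* The DISHRCH inverse is ambiguous by construction and not offered.
* Data Access Agreement legal text, authentication/identity, and FHIR
  security-label serialization are out of scope.
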
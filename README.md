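# consent-codes

Consent Codes are the controlled vocabulary used by genomic data archives,
biobanks and Data Access Committees to record the consent-based conditions
under which shared datasets and biospecimen collections may be re-used —
codes like `HMB(CC)` (health/medical/biomedical research, clinical
reference use permitted), `DS-CANCER(CC)` (cancer research only), `NPU`
(not-for-profit use only) or `GS-EU` (use within the EU only). This
package makes the v4 vocabulary executable, for data custodians and access
systems that want to validate consent metadata and pre-screen access
requests automatically rather than by expert review of each consent form:

* an audited, in-package **registry** of all 34 v4 codes (5 primary
  categories, 7 secondary modifiers, 15 requirements, 7 permissions) with
  their structural metadata;
* a **parser/validator** for code tokens (`BASE(-PARAM)?((CC))?`) and
  whole profiles — exactly one primary, scope rules such as HPOA only on
  HMB/DS, contradiction detection such as `DS-HIV` with `NDS-HIV`;
* a **decision engine**: profile × structured request →
  `PERMIT` / `PERMIT_WITH_OBLIGATIONS` / `DENY`, with fact gates
  (organization type, commercial purpose, geography, time limits, named
  approval), attestation obligations (publication, ethics approval,
  benefit sharing, return of results, embargo, …), biospecimen permission
  gating (cell lines need `CL`, nucleic-acid extraction needs `GEN`) and
  an explainable rule trace — fail-closed throughout;
* fidelity-annotated **crosswalks** to GA4GH DUO terms (2021-02-23
  release) and HL7 Purpose-of-Use codes, with the published cautions;
* **catalog tools** and a CLI to tag, validate and filter whole dataset
  catalogs by what a requester is allowed to do.

## Worked example

A cancer-specific dataset that permits clinical reference use, restricted
to not-for-profit organizations, with publication and ethics-approval
obligations — evaluated against a not-for-profit breast-cancer study that
attests to both obligations (a one-edge term hierarchy makes "breast
cancer" fall under CANCER):

```python
import consentcodes as cc

profile = cc.parse_profile(["DS-CANCER(CC)", "NPU", "PUB", "IRB"],
                           ["data"], is_genetic_resource=True)
request = cc.AccessRequest(
    purpose_domain="health",
    disease_terms={"breast cancer"},
    clinical_reference_use=True,
    requester=cc.RequesterAttributes(org_type="not_for_profit", geography="FR"),
    attestations={"PUB": True, "IRB": True},
)
matcher = cc.TermMatcher({"breast cancer": "cancer"})
print(cc.explain(cc.evaluate(profile, request, term_matcher=matcher)))
```

prints

```
decision: PERMIT_WITH_OBLIGATIONS
  ✓ [DS_DISEASE_MATCH] DS: study diseases fall under CANCER — Use of the data/biospecimen must be related to [disease]
  ✓ [CC_REQUIRED] DS: clinical reference use permitted by (CC) — Use of the data/biospecimen must be related to [disease]
  ✓ [GATE_NPU] NPU: not-for-profit requester — Use of the data/biospecimen is limited to not-for-profit organizations
  ✓ [OBLIGATION_ATTESTED] PUB: PUB attested — Requestor agrees to make results of studies using the data/biospecimen available to the larger scientific community
  ✓ [OBLIGATION_ATTESTED] IRB: IRB attested — Requestor must provide documentation of local IRB/REC approval
obligations: PUB, IRB
```

The use is permitted, conditional on the two attested obligations. Had the
requester been for-profit, the NPU gate would flip the decision to `DENY`
with a reason naming NPU; had `IRB` not been attested, the denial reason
would name exactly the missing attestation. Crosswalking the same primary:

```python
>>> e = cc.to_duo("DS-CANCER(CC)")
>>> e.target_id, e.fidelity
('DUO:0000007', 'exact')
```

From the shell, the same machinery:

```
consent-codes validate HMB(CC) HPOA PUB --genetic
consent-codes explain NDS
consent-codes decide --profile profile.json --request request.json   # exit 2 on DENY
consent-codes map --to duo DS-CANCER(CC) HPOA
consent-codes filter --catalog catalog.json --request request.json --out decisions.json
consent-codes audit-coverage
```

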
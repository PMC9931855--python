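target_id	target_name	consent_code	fidelity	caution
HRESCH	healthcare research	GRU	broader	HRESCH spans biomedical, population origins or ancestry, translational and disease/discipline-specific healthcare research; no exact equivalence to a single Consent Code is stated, GRU(CC) is the closest narrower code
BIOHRCH	biomedical research	HMB	exact
CLINTRCH	clinical trial research		none
CLINTRCHNPC	clinical trial research without patient care		none
CLINTRCHPC	clinical trial research with patient care		none
PRECLINTRCH	preclinical trial research		none
DSHRCH	disease specific healthcare research	DS	exact
DISHRCH	discipline specific healthcare research	RS	related	can be equivalent to RS-[XX], TDS-[XX], or GSO Consent Codes; the conditions distinguishing the three cases are not specified, so no inverse mapping is offered
DISHRCH	discipline specific healthcare research	TDS	related	can be equivalent to RS-[XX], TDS-[XX], or GSO Consent Codes; the conditions distinguishing the three cases are not specified, so no inverse mapping is offered
DISHRCH	discipline specific healthcare research	GSO	related	can be equivalent to RS-[XX], TDS-[XX], or GSO Consent Codes; the conditions distinguishing the three cases are not specified, so no inverse mapping is offered
POAHRCH	population origins or ancestry healthcare research	HPOA	exact
TRANSHRCH	translational healthcare research		none
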
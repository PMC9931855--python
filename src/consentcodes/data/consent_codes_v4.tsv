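id	name	tier	parameter_role	cc_suffix_allowed	applies_to	genetic_only	biospecimen_only	version_introduced	description
NRES	no restrictions	PRIMARY	none	false	data	false	false	v1	No restrictions on data use
GRU	general research use and clinical care (as reference data only)	PRIMARY	none	true	data,biospecimen	false	false	v1	For health/medical/biomedical purposes and other biological research, including the study of population origins or ancestry
HMB	health/medical/biomedical research and clinical care (as reference data only)	PRIMARY	none	true	data,biospecimen	false	false	v1	Use of the data/biospecimen is limited to health/medical/biomedical purposes, does not include the study of population origins or ancestry
DS	disease-specific research and clinical care (as reference data only)	PRIMARY	disease	true	data,biospecimen	false	false	v1	Use of the data/biospecimen must be related to [disease]
POA	population origins/ancestry research	PRIMARY	none	false	data,biospecimen	false	false	v1	Use of the data/biospecimen is limited to the study of population origins or ancestry
TDS	therapy or drug-specific research	SECONDARY	therapy_or_drug	false	data,biospecimen	false	false	v3	Use of the data/biospecimen must be related to [therapy or drug]
RS	other research-specific restrictions	SECONDARY	research_type	false	data,biospecimen	false	false	v1	Use of the data/biospecimen is limited to studies of [research type] (e.g., pediatric research)
NDS	no research into specific disease areas	SECONDARY	disease	false	data,biospecimen	false	false	v3	Use of data/biospecimen is NOT allowed for research into [certain disease areas]
HPOA	health-related POA analysis	SECONDARY	none	false	data,biospecimen	false	false	v4	Use of data/biospecimen includes analysis of population origins or ancestry ONLY as it relates to health (for HMB and DS datasets)
NMDS	no "general methods" research	SECONDARY	none	false	data	false	false	v1	Use of the data includes methods development research (e.g., development of software or algorithms) ONLY within the bounds of other data use limitations
RUO	research use only	SECONDARY	none	false	data	false	false	v1	Use of data is limited to research purposes (e.g., does not include its use in clinical care as reference data)
GSO	genetic studies only	SECONDARY	none	false	data,biospecimen	true	false	v1	Use of the data or biospecimen is limited to genetic studies only (e.g., no research using only the phenotype or other health or lifestyle data)
NPU	not-for-profit use only	REQUIREMENT	none	false	data,biospecimen	false	false	v1	Use of the data/biospecimen is limited to not-for-profit organizations
NCU	non-commercial use only	REQUIREMENT	none	false	data,biospecimen	false	false	v4	Use of the data/biospecimen is limited to non-commercial uses
BEN	benefit sharing required	REQUIREMENT	none	false	data,biospecimen	false	false	v4	Benefits resulting from use of the data/biospecimen (e.g., drug manufacturing) must be shared with the participant community
PUB	publication required	REQUIREMENT	none	false	data,biospecimen	false	false	v1	Requestor agrees to make results of studies using the data/biospecimen available to the larger scientific community
COL	collaboration required	REQUIREMENT	investigators	false	data,biospecimen	false	false	v1	Requestor must agree to collaboration with the [primary study investigator(s)]
ROR	return of results (RoR) required	REQUIREMENT	ror_policy	false	data,biospecimen	false	false	v4	Requestor must return individual research results that may be of interest to participants according to the project's [RoR policy]
RTN	return data to database/resource	REQUIREMENT	none	false	data,biospecimen	false	false	v2	Requestor must return derived/enriched data to the database/resource
IRB	ethics approval required	REQUIREMENT	none	false	data,biospecimen	false	false	v1	Requestor must provide documentation of local IRB/REC approval
GS	geographical restrictions	REQUIREMENT	geographic_region	false	data,biospecimen	false	false	v1	Use of the data/biospecimen is limited to within [geographic region]
MOR	publication moratorium/embargo	REQUIREMENT	date	false	data,biospecimen	false	false	v1	Requestor agrees not to publish results of studies until [date]
TS	time limits on use	REQUIREMENT	months	false	data,biospecimen	false	false	v1	Use of data/biospecimen is approved for [x months]
OS	approval from original study	REQUIREMENT	none	false	data,biospecimen	false	false	v4	Approval of proposed data/biospecimen use is required from the original study (in addition to data access review)
US	user-specific restrictions	REQUIREMENT	none	false	data,biospecimen	false	false	v1	Use of data/biospecimen is limited to use by approved users
PS	project-specific restrictions	REQUIREMENT	none	false	data,biospecimen	false	false	v1	Use of data/biospecimen is limited to use within an approved project
IS	institution-specific restrictions	REQUIREMENT	none	false	data,biospecimen	false	false	v1	Use of data/biospecimen is limited to use within an approved institution
CQ	recontact for questionnaire data	PERMISSION	none	false	data,biospecimen	false	false	v3	May contact patient/participant to seek consent to provide questionnaire data
CS	recontact for sampling	PERMISSION	none	false	data,biospecimen	false	false	v3	May contact patient/participant to seek consent to provide additional samples
CR	recontact for additional research	PERMISSION	none	false	data,biospecimen	false	false	v3	May contact patient/participant to seek consent to participate in additional research
HR	access to patient medical record	PERMISSION	none	false	data,biospecimen	false	false	v3	The patient/participant has provided consent for access to some data from the patient medical record for research purposes
ARA	associated resources available	PERMISSION	repository_link	false	data,biospecimen	false	false	v4	Biospecimens or data from the same individual(s) are available from the following [repository/link]
GEN	genetic analysis	PERMISSION	none	false	biospecimen	false	true	v4	May extract DNA, RNA and micro-RNA from biospecimens
CL	cell-lines	PERMISSION	none	false	biospecimen	false	true	v4	May produce cell-lines (including stem cells) from biospecimens
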
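consent_code	target_id	fidelity	caution
NRES	DUO:0000004	exact
GRU	DUO:0000005	exact	not to be confused with the much broader GRU DUO term DUO:0000042
HMB	DUO:0000006	exact
DS	DUO:0000007	exact
POA	DUO:0000011	exact
TDS		none
RS	DUO:0000012	exact
NDS		none
HPOA		none
NMDS		none	The DUO NMDS term DUO:0000015 prohibits any methods development research
RUO	DUO:0000014	exact
GSO	DUO:0000016	exact
NPU	DUO:0000045	exact
NCU		none	The DUO NCU term DUO:0000046 defines non-commercial use as data can be used by commercial organisations for research purposes, but not commercial purposes.
BEN		none
PUB	DUO:0000019	exact
COL	DUO:0000020	exact
ROR		none
RTN	DUO:0000029	exact
IRB	DUO:0000021	exact
GS	DUO:0000022	exact
MOR	DUO:0000024	exact
TS	DUO:0000025	exact
OS		none
US	DUO:0000026	exact
PS	DUO:0000027	exact
IS	DUO:0000028	exact
CQ		none
CS		none
CR		none
HR		none
ARA		none
GEN		none
CL		none
	DUO:0000042	none	broader than GRU(CC): general research use without the reference-data-only clinical care permission scope
	DUO:0000015	none	prohibits any methods development research, unlike NMDS which permits it within the bounds of other data use limitations
	DUO:0000046	none	defines non-commercial use as data can be used by commercial organisations for research purposes, but not commercial purposes
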
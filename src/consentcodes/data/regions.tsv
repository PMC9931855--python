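region	member
EU	AT
EU	BE
EU	BG
EU	HR
EU	CY
EU	CZ
EU	DK
EU	EE
EU	FI
EU	FR
EU	DE
EU	GR
EU	HU
EU	IE
EU	IT
EU	LV
EU	LT
EU	LU
EU	MT
EU	NL
EU	PL
EU	PT
EU	RO
EU	SK
EU	SI
EU	ES
EU	SE
EEA	AT
EEA	BE
EEA	BG
EEA	HR
EEA	CY
EEA	CZ
EEA	DK
EEA	EE
EEA	FI
EEA	FR
EEA	DE
EEA	GR
EEA	HU
EEA	IE
EEA	IT
EEA	LV
EEA	LT
EEA	LU
EEA	MT
EEA	NL
EEA	PL
EEA	PT
EEA	RO
EEA	SK
EEA	SI
EEA	ES
EEA	SE
EEA	IS
EEA	LI
EEA	NO
NORTH_AMERICA	US
NORTH_AMERICA	CA
NORTH_AMERICA	MX
AFRICA	DZ
AFRICA	AO
AFRICA	BJ
AFRICA	BW
AFRICA	BF
AFRICA	BI
AFRICA	CV
AFRICA	CM
AFRICA	CF
AFRICA	TD
AFRICA	KM
AFRICA	CG
AFRICA	CD
AFRICA	CI
AFRICA	DJ
AFRICA	EG
AFRICA	GQ
AFRICA	ER
AFRICA	SZ
AFRICA	ET
AFRICA	GA
AFRICA	GM
AFRICA	GH
AFRICA	GN
AFRICA	GW
AFRICA	KE
AFRICA	LS
AFRICA	LR
AFRICA	LY
AFRICA	MG
AFRICA	MW
AFRICA	ML
AFRICA	MR
AFRICA	MU
AFRICA	MA
AFRICA	MZ
AFRICA	NA
AFRICA	NE
AFRICA	NG
AFRICA	RW
AFRICA	ST
AFRICA	SN
AFRICA	SC
AFRICA	SL
AFRICA	SO
AFRICA	ZA
AFRICA	SS
AFRICA	SD
AFRICA	TZ
AFRICA	TG
AFRICA	TN
AFRICA	UG
AFRICA	ZM
AFRICA	ZW
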
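list_name	sublist	gene
er_proteostasis	chaperones	HSPA5
er_proteostasis	chaperones	HSP90B1
er_proteostasis	chaperones	CALR
er_proteostasis	chaperones	CANX
er_proteostasis	chaperones	PDIA3
er_proteostasis	chaperones	P4HB
er_proteostasis	chaperones	DNAJC10
er_proteostasis	glycoproteostasis	DDOST
er_proteostasis	glycoproteostasis	DAD1
er_proteostasis	glycoproteostasis	RPN1
er_proteostasis	glycoproteostasis	RPN2
er_proteostasis	glycoproteostasis	STT3A
er_proteostasis	glycoproteostasis	MOGS
er_proteostasis	degradation	SEL1L
er_proteostasis	degradation	SYVN1
er_proteostasis	degradation	UFD1
er_proteostasis	degradation	NGLY1
er_proteostasis	targeting	SRP68
er_proteostasis	targeting	SRP72
er_proteostasis	targeting	SRP54
er_proteostasis	targeting	SEC61A1
er_proteostasis	targeting	SEC61B
mito_proteostasis	chaperones	HSPA9
mito_proteostasis	chaperones	HSPE1
mito_proteostasis	chaperones	HSPD1
mito_proteostasis	chaperones	TRAP1
mito_proteostasis	chaperones	DNAJA3
mito_proteostasis	chaperones	GRPEL1
mito_proteostasis	proteases	LONP1
mito_proteostasis	proteases	CLPP
mito_proteostasis	proteases	CLPX
mito_proteostasis	proteases	AFG3L2
mito_proteostasis	proteases	SPG7
mito_proteostasis	proteases	HTRA2
mito_proteostasis	proteases	OMA1
mito_proteostasis	proteases	YME1L1
mito_proteostasis	import	TIMM23
mito_proteostasis	import	TIMM23B
mito_proteostasis	import	TIMM17A
mito_proteostasis	import	TIMM44
mito_proteostasis	import	TOMM22
mito_proteostasis	import	TOMM40
mito_proteostasis	import	TOMM70
mito_proteostasis	import	PAM16
mito_proteostasis	import	DNAJC19
mito_proteostasis	import	SAMM50
mito_proteostasis	import	PHB2
mitocarta	proteostasis	HSPA9
mitocarta	proteostasis	HSPE1
mitocarta	proteostasis	HSPD1
mitocarta	proteostasis	LONP1
mitocarta	proteostasis	CLPP
mitocarta	proteostasis	TIMM23B
mitocarta	proteostasis	TOMM22
mitocarta	proteostasis	PHB2
mitocarta	trna_synthetases	IARS2
mitocarta	trna_synthetases	VARS2
mitocarta	trna_synthetases	WARS2
mitocarta	transporters	PRELID3B
mitocarta	transporters	SLC25A42
mitocarta	transporters	SLC25A3
mitocarta	oxphos	NDUFA9
mitocarta	oxphos	SDHB
mitocarta	oxphos	UQCRC1
mitocarta	oxphos	COX4I1
mitocarta	oxphos	ATP5F1A
mitocarta	dynamics	MFN2
mitocarta	dynamics	OPA1
mitocarta	dynamics	DNM1L
mitocarta	mtdna	TFAM
mitocarta	mtdna	POLG
mitocarta	mtdna	SSBP1
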
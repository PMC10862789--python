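ISR	synthetic stand-in panel: ATF4-driven integrated stress response targets	DDIT3	ATF3	TRIB3	CHAC1	ASNS	PPP1R15A	SESN2	DDIT4	PCK2	SLC7A11	NUPR1	GDF15	STC2
UPR	synthetic stand-in panel: ER unfolded protein response targets (ATF6 + IRE1/XBP1s arms)	HSPA5	HSP90B1	HERPUD1	PDIA4	HYOU1	MANF	CRELD2	SDF2L1	SEL1L	PDIA6	DNAJB9	EDEM1	DNAJB11	DERL3	SEC24D	SSR1	TMED9	YIF1A	SRPRB	TMEM165
HSR	synthetic stand-in panel: HSF1-driven heat shock response targets	HSPA1A	HSPA1B	HSPB1	DNAJB1	HSPH1	HSPA4L	BAG3	CHORDC1	DNAJA1	HSP90AA1	HSPA6	SERPINH1
OSR	synthetic stand-in panel: NRF2-driven oxidative stress response targets	HMOX1	NQO1	GCLM	GCLC	TXNRD1	GSR	FTL	FTH1	SRXN1	ME1	OSGIN1	ABCB6
ATF6	synthetic stand-in panel: ATF6-arm UPR targets	HSPA5	HSP90B1	HERPUD1	PDIA4	HYOU1	MANF	CRELD2	SDF2L1	SEL1L	PDIA6
IRE1_XBP1s	synthetic stand-in panel: IRE1/XBP1s-arm UPR targets	DNAJB9	EDEM1	DNAJB11	DERL3	SEC24D	SSR1	TMED9	YIF1A	SRPRB	TMEM165
CONTROL	synthetic stand-in panel: stably expressed reference genes	ACTB	GAPDH	TUBB	PPIA	PGK1	RPLP0	B2M	GUSB	HPRT1	TBP	UBC	YWHAZ	SDHA	RPL13A	RPS18	PUM1	EMC7	VCP	PSMB4
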
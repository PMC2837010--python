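aggressive_tumor_signature	42-gene v-Src inducible aggressive tumor signature	ATAD3A	C13orf3	CCNA2	CCNE2	CEP55	CSTA	E2F8	EAF2	EXO1	GAR1	HELLS	HMOX1	HSP90AB1	IL8	ITGA4	KIF11	KIF2A	LBR	MPP1	NASP	NOC2L	NOP14	NPM3	ODC1	PDCD6	PLAU	RIOK3	RRM1	RRM2	SHC4	SLC2A14	SLC2A3	SLC36A4	SOCS1	TRIP13	TTC35	UHRF1	UPP1	USP1	USP18	VRK1	ZDHHC21
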
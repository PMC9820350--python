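gene_id	psp_type	rpkm	published_percent
POP_Tc	POP	0	0
DPP4.1_Tc	DPP4	1688	25.1
DPP4.2_Tc	DPP4	533	7.9
DPP8_Tc	DPP8	75	1.1
DPP10.1_Tc	DPP10	8	-
DPP10.2_Tc	DPP10	5	-
PRCP.1_Tc	PRCP	27	0.4
PRCP.2_Tc	PRCP	675	10.0
APP1.1_Tc	APP1	2420	35.9
APP1.2_Tc	APP1	8	0.1
APP3_Tc	APP3	58	0.9
XPD_Tc	XPD	1254	18.6
LAP.1_Tc	LAP	86	-
CND_Tc	CND	2462	-
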
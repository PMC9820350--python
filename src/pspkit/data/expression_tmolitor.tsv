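gene_id	psp_type	rpkm	published_percent
POP_Tm	POP	25	4.2
DPP4.1_Tm	DPP4	147	24.6
DPP4.2_Tm	DPP4	102	17.1
DPP8_Tm	DPP8	20	3.3
DPP10.1_Tm	DPP10	370	-
DPP10.2_Tm	DPP10	7	-
PRCP_Tm	PRCP	53	8.9
APP1_Tm	APP1	88	14.7
APP2_Tm	APP2	3	0.5
APP3_Tm	APP3	12	2.0
XPD_Tm	XPD	148	24.7
LAP_Tm	LAP	15	-
CND_Tm	CND	625	-
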
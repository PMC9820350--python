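family	reference_id	role	position	expected
S9A	P48147	catalytic	554	S
S9A	P48147	catalytic	641	D
S9A	P48147	catalytic	680	H
S9A	P48147	S1	595	W
S9A	P48147	S1	476	F
S9A	P48147	S1	644	V
S9A	P48147	S1	580	V
S9A	P48147	S1	599	Y
S9A	P48147	S1	473	Y
S9A	P48147	S2	643	R
S9A	P48147	S3	173	F
S9A	P48147	S3	235	MR
S9A	P48147	S3	255	C
S9A	P48147	S3	591	I
S9A	P48147	S3	594	A
S9A	P48147	motif	0	NGGSNGG
S9A	P48147	motif	0	ADHDDRV
S9A	P48147	motif	0	RAGHGAG
S9B	P27487	catalytic	630	S
S9B	P27487	catalytic	708	D
S9B	P27487	catalytic	740	H
S9B	P27487	S1	631	Y
S9B	P27487	S1	656	V
S9B	P27487	S1	659	WLF
S9B	P27487	S1	662	Y
S9B	P27487	S1	666	Y
S9B	P27487	S1	711	V
S9B	P27487	S2	710	N
S9B	P27487	S2	125	R
S9B	P27487	S2	205	E
S9B	P27487	S2	206	E
S9B	P27487	determinant	663	DN
S28	P42785	catalytic	179	S
S28	P42785	catalytic	430	D
S28	P42785	catalytic	455	H
S28	P42785	S1	183	M
S28	P42785	S1	359	W
S28	P42785	S1	369	M
S28	P42785	S1	432	W
M24B	Q9NQW7	metal	415	D
M24B	Q9NQW7	metal	426	D
M24B	Q9NQW7	metal	489	H
M24B	Q9NQW7	metal	523	E
M24B	Q9NQW7	metal	537	E
M17	P28838	metal	282	K
M17	P28838	metal	287	D
M17	P28838	metal	294	K
M17	P28838	metal	305	D
M17	P28838	metal	364	D
M17	P28838	metal	366	E
M17	P28838	metal	368	R
M20	Q96KP4	metal	99	H
M20	Q96KP4	metal	101	D
M20	Q96KP4	metal	132	D
M20	Q96KP4	metal	166	E
M20	Q96KP4	metal	167	E
M20	Q96KP4	metal	195	D
M20	Q96KP4	metal	228	H
M20	Q96KP4	metal	445	H
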
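complex	designation	subject_interface	partner_interface	bfe_mean	bfe_sem
CXCR2-CXCR2	AF-3	TM4, TM5	Identical	-70.52	0.14
CXCR2-CXCR2	CP-12	TM1, TM2, TM3 (E)	Identical	-69.82	0.33
CXCR2-CXCR1	CP-H18	TM7, TM6, TM1	TM4, TM5	-118.83	0.19
CXCR2-CXCR1	CP-14	TM1, TM2, TM3 (E)	TM7, TM1, TM6	-110.32	0.23
CXCR2-Iso_2TM	CP-17	TM6, TM7, TM1	TM2, TM1	-133.80	0.18
CXCR2-Iso_2TM	CP-16	TM4, TM5	TM1, TM2	-104.69	0.29
CXCR2-Iso_3TM	CP-10	TM7, TM1, TM6	TM2, TM1, TM3 (E)	-123.76	0.22
CXCR2-Iso_4TM	AF-5	TM6, TM7 (E)	TM1, TM2 (E), TM3 (E)	-105.62	0.19
CXCR2-Iso_4TM	CP-28	TM5, TM4, TM6	TM1, TM2, TM3	-96.96	0.20
CXCR7-CXCR7	CP-H8	TM6, TM7, TM1 (M)	Identical	-160.12	0.41
CXCR7-CXCR4	CP-19	TM7, TM6, TM1	TM5, TM4	-150.17	0.21
CXCR7-Iso_4TM	CP-H14	TM2, TM1, TM3 (E), TM4 (M)	TM1, TM2, TM3	-104.81	0.16
CCR2-CCR2	AF-1	TM4, TM5, TM3 (I)	Identical	-44.84	0.16
CCR2-CCR2	CP-11	TM2, TM1, TM3 (E), TM4 (I)	Identical	-39.61	0.26
CCR2-CXCR4	AF-2	TM6, TM7, TM5	TM6, TM5	-100.08	0.29
CCR2-CXCR4	AF-5	TM5, TM4, TM3 (I)	Identical	-98.45	0.14
CCR2-CCR5	CP-11	TM2, TM1, TM3 (E), TM4 (I)	TM7, TM1, TM6	-143.84	0.24
CCR2-CCR5	AF-2	TM5, TM4, TM3 (I)	Identical	-121.76	0.14
CCR2-Iso_2TM	CP-13	TM2, TM1, TM3 (E), TM4 (I)	TM1, TM2	-149.04	0.35
CCR2-Iso_2TM	CP-18	TM7, TM6, TM1	TM1, TM2	-103.16	0.22
CCR7-CCR7	AF-2	TM7, TM1	Identical	-118.45	0.21
CCR7-CXCR4	AF-2	TM7, TM6	TM6, TM7	-127.24	0.26
CCR7-CXCR4	AF-4	TM1, TM7 (I)	TM4, TM5	-119.23	0.36
CCR7-CXCR4	CP-19	TM5, TM4, TM3 (I)	Identical	-117.10	0.13
CCR7-Iso_5TM	CP-H18	TM1, TM7, TM2	TM2, TM1, TM3, TM5	-152.19	0.29
CCR7-Iso_5TM	CP-H10	TM5, TM4, TM3 (E)	TM5, TM4, TM1, TM2	-140.47	0.22
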
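dimer_complex	dimer_model	blocker_complex	blocker_model	shared_helices	reported_blocks
CXCR2-CXCR2	AF-3	CXCR2-Iso_2TM	CP-16	4,5	true
CXCR2-CXCR2	AF-3	CXCR2-Iso_4TM	CP-28	4,5	true
CXCR2-CXCR1	CP-H18	CXCR2-Iso_2TM	CP-17	6,7,1	true
CXCR2-CXCR1	CP-H18	CXCR2-Iso_3TM	CP-10	6,7,1	true
CXCR2-CXCR1	CP-H18	CXCR2-Iso_4TM	AF-5	6,7	true
CXCR7-CXCR7	CP-H8	CXCR7-Iso_4TM	CP-H14	none	false
CCR2-CCR2	CP-11	CCR2-Iso_2TM	CP-13	1,2,3,4	true
CCR2-CCR5	CP-11	CCR2-Iso_2TM	CP-13	1,2,3,4	true
CCR2-CXCR4	AF-2	CCR2-Iso_2TM	CP-18	6,7	true
CCR7-CCR7	AF-2	CCR7-Iso_5TM	CP-H18	1,7	true
CCR7-CXCR4	AF-2	CCR7-Iso_5TM	CP-H18	7	true
CCR7-CXCR4	AF-4	CCR7-Iso_5TM	CP-H18	1,7	true
CCR7-CXCR4	CP-19	CCR7-Iso_5TM	CP-H10	3,4,5	true
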
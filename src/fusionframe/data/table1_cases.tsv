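case_id	age	sex	location	methylation_class	integrated_diagnosis	goi
1	4	F	Right temporal	LGG_MYB_D	Angiocentric glioma	MYB
2	64	F	Left frontal	AG_MYB	Angiocentric glioma	MYB
3	2	M	Left parietal	LGG_MYB_D	Diffuse astrocytoma, MYB- or MYBL1-altered	MYB
4	8	M	Left parieto-occipital	LGG_MYB_C	Diffuse astrocytoma, MYB- or MYBL1-altered	MYB
5	18	M	Right temporal	AG_MYB	Angiocentric glioma	MYB
6	51	M	Left parietal	LGG_MYB_C	Diffuse astrocytoma, MYB- or MYBL1-altered	MYB
7	21	M	Right frontal	LGG_MYB_B	Angiocentric glioma	MYB
8	36	M	Left pontine	LGG_MYB_B	Diffuse astrocytoma, MYB- or MYBL1-altered	MYB
9	9	F	Left temporal	AG_MYB	Angiocentric glioma	MYB
10	1	M	Left frontal	LGG_MYB_D	Diffuse astrocytoma, MYB- or MYBL1-altered	MYBL1
11	3	M	Right parietal	LGG_MYB_D	Diffuse astrocytoma, MYB- or MYBL1-altered	MYBL1
12	6	M	Right insular	LGG_MYB_D	Diffuse astrocytoma, MYB- or MYBL1-altered	MYBL1
13	19	F	Left temporal	AG_MYB	Angiocentric glioma	MYBL1
14	14	F	Left parietal	LGG_MYB_C	Diffuse astrocytoma, MYB- or MYBL1-altered	MYBL1
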
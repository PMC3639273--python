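network_id	figure_index	label	brodmann	hemisphere	x	y	z
N1	1	Precentral gyrus (MI, BA 4)	4	L	-30	-30	58
N1	2	Precentral gyrus (MI, BA 4)	4	R	34	-24	52
N1	3	Postcentral gyrus (SI, BA 1/3)	1/3	L	-36	-40	70
N1	4	Postcentral gyrus (SI, BA 1/3)	1/3	R	38	-30	66
N1	5	Middle frontal gyrus (SMA, BA 6)	6	L	-4	-10	60
N1	6	Middle frontal gyrus (SMA, BA 6)	6	R	6	-12	58
N1	7	Precentral gyrus (PMd, BA 6)	6	L	-36	-12	66
N1	8	Precentral gyrus (PMd, BA 6)	6	R	28	-16	64
N1	9	Cerebellar hemisphere (IV-V)	IV-V	L	-20	-46	-24
N1	10	Cerebellar hemisphere (IV-V)	IV-V	R	24	-44	-26
N1	11	Cerebellar vermis (IV-V)	IV-V	L	-2	-60	-16
N1	12	Cerebellar vermis (IV-V)	IV-V	R	2	-48	-4
N1	13	Parietal operculum (SII, BA 43)	43	L	-46	-28	22
N1	14	Superior temporal gyrus (AI, BA 41)	41	L	-46	-36	24
N1	15	Supramarginal gyrus (SI, BA 2)	2	L	-56	-26	36
N1	16	IFG (pars opercularis, BA 44)	44	R	60	10	12
N1	17	Parietal operculum (SII, BA 43)	43	R	46	-26	20
N1	18	Superior temporal gyrus (AI, BA 41)	41	R	58	-30	20
N1	19	Supramarginal gyrus (SI, BA 2)	2	R	54	-32	32
N1	20	Precentral gyrus (PMv, BA 6)	6	R	58	8	40
N1	21	IFG (pars opercularis, BA 44)	44	L	-54	4	0
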
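network_id	figure_index	label	brodmann	hemisphere	x	y	z
N2	1	Superior frontal gyrus (SMA, BA 6)	6	L	-10	-18	64
N2	2	Superior frontal gyrus (SMA, BA 6)	6	R	12	-20	66
N2	3	Parietal operculum (SII, BA 43)	43	L	-60	-28	28
N2	4	Superior temporal gyrus (AII, BA 22)	22	L	-66	-16	12
N2	5	Parietal operculum (SII, BA 43)	43	R	68	-12	14
N2	6	Superior temporal gyrus (AII, BA 22)	22	R	66	-14	10
N2	7	IFG (pars opercularis, BA 44)	44	L	-58	12	2
N2	8	IFG (pars opercularis, BA 44)	44	R	62	20	4
N2	9	Inferior parietal cortex (BA 40)	40	L	-40	-44	52
N2	10	Middle frontal gyrus (DLPFC, BA 46)	46	R	34	34	38
N2	11	Middle cingulate cortex (BA 23)	23	L	-2	-16	44
N2	12	Middle cingulate cortex (BA 23)	23	R	4	-8	42
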
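cell	chrom	start_mb	end_mb	size_mb	direction	cnv_class	start_terminal	end_terminal	fragile_start	fragile_end
1	chr5	0	26	26	gain	segmental	1	0	.	FRA5E
1	chr12	0	48	48	gain	segmental	1	0	.	FRA12A
1	chr16	0	29	29	gain	segmental	1	0	.	FRA6E
1	chr20	0	11.5	11.5	gain	segmental	1	0	.	FRA20B
1	chr21	33	46.5	13.5	gain	segmental	0	1	none	.
1	chrX	57.5	81.5	24	gain	segmental	0	0	none	none
2	chr3	60.5	69.5	9	gain	segmental	0	0	FRA3B	none
3	chr3	60.5	69.5	9	gain	segmental	0	0	FRA3B	none
4	chr3	60.5	69.5	9	gain	segmental	0	0	FRA3B	none
4	chr11	68	82	14	gain	segmental	0	0	none	FRA11EH
5	chr3	60.5	69.5	9	gain	segmental	0	0	FRA3B	none
5	chr4	119.5	129.5	10	gain	segmental	0	0	none	none
5	chr13	50	59	9	gain	segmental	0	0	none	FRA13b
6	chr1	35.5	150.5	115	gain	segmental	0	0	none	FRA1F
6	chr2	158.5	242	83.5	loss	segmental	0	1	none	.
6	chr4	0	54.5	54.5	gain	segmental	1	0	.	FRA4b
6	chr4	118	190	72	gain	segmental	0	1	none	.
6	chr9	95	138.5	43.5	loss	segmental	0	1	none	.
6	chr10	104	134	30	gain	segmental	0	1	FRA10A	.
6	chr14	0	107	107	gain	whole_chromosome	1	1	.	.
6	chr16	0	90	90	gain	whole_chromosome	1	1	.	.
6	chr17	27.5	58.5	31	gain	segmental	0	0	none	FRA17B
7	chr11	68.5	95.5	27	gain	segmental	0	0	FRA11EH	none
8	chr1	30	94	64	gain	segmental	0	0	FRA1D	FRA1M
8	chr12	100	133	33	gain	segmental	0	1	none	.
9	chr3	38.5	120.5	82	loss	segmental	0	0	none	none
9	chr3	149.5	198.5	49	gain	segmental	0	1	FRA3D	.
9	chr5	79	181.5	102.5	loss	segmental	0	1	none	.
9	chr7	69	159.5	90.5	loss	segmental	0	1	FRA7J	.
9	chr12	106	133.5	27.5	loss	segmental	0	1	none	.
9	chr16	81	90	9	loss	segmental	0	1	FRA16D	.
10	chr3	137.5	198.5	61	loss	segmental	0	1	none	.
10	chr4	105	142	37	gain	segmental	0	0	none	none
10	chr7	16.5	52	35.5	gain	segmental	0	0	none	none
11	chr7	0	87	87	gain	segmental	1	0	.	none
12	chr1	0	249	249	loss	whole_chromosome	1	1	.	.
12	chr2	0	40	40	loss	segmental	1	0	.	none
12	chr2	98	134.5	36.5	gain	segmental	0	0	FRA2A	FRA2S-2F
12	chr2	164	242	78	loss	segmental	0	1	none	.
12	chr4	0	190	190	loss	whole_chromosome	1	1	.	.
12	chr5	75.5	181.5	106	loss	segmental	0	1	none	.
12	chr7	0	159.5	159.5	loss	whole_chromosome	1	1	.	.
12	chr8	0	39	39	loss	segmental	1	0	.	none
12	chr8	103	145	42	gain	segmental	0	1	FRA8A	.
12	chr10	0	134	134	loss	whole_chromosome	1	1	.	.
12	chr12	0	133	133	gain	whole_chromosome	1	1	.	.
12	chr14	38.5	73	34.5	loss	segmental	0	0	none	none
12	chr18	0	54.5	54.5	gain	segmental	1	0	.	FRA18B
12	chr19	0	58.5	58.5	loss	whole_chromosome	1	1	.	.
13	chr16	31.5	55	23.5	loss	segmental	0	0	none	none
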
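# Distribution of re-edited grey seal mtDNA haplotypes across Baltic breeding
# sites, plus auxiliary-dataset counts and the repository haplotype ids each
# re-edited haplotype matches ("New" = no repository match).
haplotype	BB	EST	STA	aux	old_id
HT1	4	5	3	14	5, 28
HT2	4	4	3	2	19, 21, 29
HT3	3	3	3	3	New
HT4	1	3	5	5	23
HT5	3	3		3	27
HT6	2	1	2	16	38
HT7	3	1		3	New
HT8	1	1	1		New
HT9	2	1			14
HT10	1	1	1		New
HT11	1	1	1	2	New
HT12	2	1			11, 17
HT13	1	2		2	16, 25
HT14			2	1	New
HT15		2			New
HT16	1	1			24
HT17			2	2	New
HT18	1	1		4	7, 9
HT19	1	1			18
HT20			2		New
HT21	1				12
HT22	1				15
HT23	1				20
HT24	1			1	New
HT25	1			1	New
HT26	1			1	New
HT27	1				New
HT28	1			1	New
HT29		1			22
HT30		1			New
HT31		1			New
HT32		1			New
HT33			1		New
HT34			1	1	New
HT35			1		3
HT36				3	31, 32, 37, 40
HT37				20	34
HT38				4	35
Total	39	36	28
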
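sample_id	museum_id	venom_type	sex	svl_mm	mass_g	state	county	platform	read_pairs	merged_reads	biosample
CLP1930	ASNHC14997	A	F	724	195	NM	Hidalgo	MiSeq	15,649,085	13,083,925	SAMN08596271
CLP1936	ASU36035	A	F	441	48	AZ	Graham	MiSeq	20,835,668	18,182,033	SAMN08596272
CLP1959	ASU36061	A	M	730	204	AZ	Yavapai	MiSeq	20,577,779	17,091,930	SAMN08596273
CLP1961	ASU36062	A	M	564	90	AZ	Yavapai	HiSeq	11,929,639	10,061,262	SAMN08596274
CLP1972	ASU36092	A	M	635	126	AZ	Pima	MiSeq	13,168,704	11,521,499	SAMN08596275
CLP1831	ASU36089	B	F	795	344	AZ	Pima	HiSeq	15,448,552	13,526,047	SAMN08596267
CLP1835	ASU36102	B	F	685	146	AZ	Pinal	HiSeq	16,271,477	14,210,557	SAMN08596269
CLP2136	ASU36103	B	M	1030	627	AZ	Pinal	MiSeq	7,771,613	6,864,270	SAMN08596277
CLP2142	ASU36104	B	M	775	262	AZ	Pinal	MiSeq	10,039,268	8,893,097	SAMN08596278
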
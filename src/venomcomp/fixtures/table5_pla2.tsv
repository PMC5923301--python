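specimen	Pla2gA1	Pla2gB1	Pla2gK	Pla2gA2-MTXA	Pla2gB2-MTXB	PLA2-6
C. atrox	+	+	+	-	-	-
C. atrox	+	+	+	-	-	-
C. adamanteus	+	+	-	-	-	-
C. scutulatus	+	-	-	+	+	-
CLP1930A	55,212.77	-	-	603,261.66	294,142.52	47,256.79
CLP1936A	242,536.57	-	-	492,462.39	264,770.94	-
CLP1959A	214.27	101,885.11	6162.67	355,273.29	166,449.59	369,588.5
CLP1961A	-	-	-	464,139.64	323,205.86	212,285.6
CLP1972A	-	-	-	520,518.57	216,000.5	263,309.5
CLP1831B	-	370,853.15	13,305.52	-	-	600,310.86
CLP1835B	320,034.14	297,244.14	18,761.21	-	-	58,732.73
CLP2136B	-	283,162.92	6014.01	-	-	709,003.82
CLP2142B	-	253,634.76	6285.41	-	-	738,317.63
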
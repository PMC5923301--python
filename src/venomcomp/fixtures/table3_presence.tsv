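toxin	CLP1930	CLP1936	CLP1959	CLP1961	CLP1972	CLP1831	CLP1835	CLP2136	CLP2142
CTL-1	-	-	+	+	-	+	+	+	+
CTL-2	-	-	+	+	-	+	+	+	+
CTL-3	-	-	-	-	-	+	+	+	+
CTL-4	-	-	-	-	-	+	+	+	+
CTL-5	-	-	+	+	-	+	+	+	+
CTL-6	-	-	+	+	-	+	+	+	+
CTL-7	-	-	+	+	-	+	+	+	+
CTL-8	-	-	+	+	+	+	+	+	+
CTL-9	+	+	+	+	+	+	-	-	+
CTL-10	-	-	+	+	+	+	+	+	+
CTL-11	-	-	+	+	-	+	+	+	+
CTL-12	+	+	+	+	+	+	+	-	-
CTL-13	-	-	+	+	-	+	+	+	+
CTL-14	-	+	+	+	+	+	+	+	+
CTL-16	+	+	+	+	+	+	-	+	+
CTL-17	-	-	-	-	-	-	-	+	+
CTL-19	+	+	+	+	+	-	+	-	+
CTL-20	-	-	-	-	-	-	-	-	+
CTL-21	-	-	-	-	-	+	+	+	+
CTL-22	-	-	-	-	-	+	+	+	+
CTL-23	+	+	+	+	+	+	+	-	+
MYO-3	-	-	-	+	-	-	+	+	+
MYO-5	-	+	-	-	-	+	-	+	+
MYO-6	-	-	-	-	-	-	-	-	+
MYO-7	-	-	-	-	-	-	-	-	+
MYO-8	-	+	+	-	-	-	-	-	-
Pla2gA1	+	+	+	-	-	-	+	-	-
Pla2gB1	-	-	+	-	-	+	+	+	+
Pla2gK	-	-	+	-	-	+	+	+	+
Pla2gA2-MTXA	+	+	+	+	+	-	-	-	-
Pla2gB2-MTXB	+	+	+	+	+	-	-	-	-
PLA2-6	+	-	+	+	+	+	+	+	+
SVMPII-1	-	-	-	-	-	+	+	+	+
SVMPIII-1	-	-	-	-	-	+	+	+	+
SVMPIII-2	-	+	+	+	+	+	+	+	+
SVMPIII-3	-	-	-	-	-	+	+	+	+
SVMPIII-5	-	-	-	-	-	+	+	+	+
SVMPIII-6	-	-	-	-	-	+	+	+	+
SVMPIII-7	-	-	-	-	-	+	+	+	+
SVMPIII-8	-	-	-	-	-	-	-	+	-
SVMPIII-9	-	-	-	-	-	+	+	+	+
SVMPIII-10	-	-	-	-	-	+	+	+	+
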
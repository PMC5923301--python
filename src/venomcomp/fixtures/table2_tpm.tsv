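toxin	CLP1930	CLP1936	CLP1959	CLP1961	CLP1972	CLP1831	CLP1835	CLP2136	CLP2142
BPP-1	140,915.97	42,576.13	83,149.6	63,491.95	45,783.43	152,393.13	126,252.15	206,001.59	140,706.64
CRISP-1	4835.29	4825.49	15,386.6	7108.63	5075.55	4047.71	4625.53	2879.87	3386.38
CTL-1	0.00	3.65	14,629.20	25,897.00	0.00	17,494.71	26,507.89	18,545.42	44,489.80
CTL-2	0.00	1.98	12,439.65	20,441.04	0.00	18,825.37	22,039.29	18,679.67	43,789.90
CTL-3	1.12	0.00	0.31	10.11	0.00	12,805.18	13,046.93	13,965.96	21,899.71
CTL-4	0.00	0.45	0.00	3.20	0.00	12,605.98	15,574.61	11,584.92	16,750.81
CTL-5	0.41	2.52	7965.07	10,951.63	0.00	4218.11	11,546.02	10,057.03	10,667.89
CTL-6	0.40	1.26	11,399.06	12,437.39	0.00	3461.60	3578.61	9394.12	10,374.16
CTL-7	0.38	1.44	7423.12	8508.27	0.00	4653.94	10,065.04	9327.24	10,662.63
CTL-8	22.39	8.78	7498.38	9084.97	232.76	2273.74	4494.79	6799.15	11,587.90
CTL-9	3859.43	4539.36	9932.82	10,002.06	3012.54	1561.25	2.48	1.52	2634.56
CTL-10	10.63	4.93	7658.06	9102.48	84.69	2499.90	3293.65	6962.90	3823.74
CTL-11	0.00	0.47	2744.48	3752.74	0.00	2814.96	6914.87	4523.03	5131.21
CTL-12	3604.05	3074.72	6797.37	6941.60	2123.74	1975.31	14.78	24.72	40.48
CTL-13	0.00	0.41	2379.11	2630.23	0.00	947.76	3008.94	1948.93	2122.28
CTL-14	0.88	171.20	883.68	555.05	147.92	637.66	1994.47	2157.31	2572.39
CTL-15	995.02	292.59	809.42	726.11	910.53	1168.87	748.84	1791.77	1309.00
CTL-16	1246.38	418.83	2132.33	2473.36	472.09	433.29	0.55	234.84	342.16
CTL-17	0.00	0.00	0.41	8.06	0.00	4.34	10.41	51.78	6202.50
CTL-18	325.45	305.49	4026.88	247.89	201.87	279.93	274.45	36.75	527.21
CTL-19	28.46	1045.78	2968.50	60.46	395.23	49.87	213.36	285.33	172.05
CTL-20	0.00	0.00	0.00	0.87	0.00	0.00	0.00	1.60	1233.72
CTL-21	0.40	0.00	0.53	11.61	0.00	59.06	27.62	511.53	361.34
CTL-22	0.00	0.00	0.38	29.57	0.00	51.73	54.86	280.15	438.68
CTL-23	3.52	9.49	15.25	7.90	45.56	5.09	13.42	1.34	9.87
HYAL-1	557.54	304.13	1309.25	379.62	221.07	468.14	408.71	436.41	222.96
KUN-1	178.35	48.25	168.92	123.70	71.34	107.63	147.09	195.49	122.11
KUN-2	14.96	4.32	13.36	14.48	5.19	20.25	20.77	20.98	12.38
LAAO-1	5188.99	2817.21	20,588.57	9120.95	1626.36	5792.61	10,578.38	6868.00	5503.11
MYO-1	1220.73	549,957.26	1072.89	27.84	457,306.12	209,616.39	44.93	44.14	29,489.77
MYO-2	6119.03	49,381.65	2467.88	3325.84	95,421.49	27,536.10	2903.51	6987.97	3925.07
MYO-3	0.00	0.00	0.00	34,019.55	0.00	0.00	87,549.28	30.87	33,694.44
MYO-4	5843.47	3702.71	12,274.75	19,693.00	497.74	1611.10	10,899.95	2894.17	4002.29
MYO-5	0.00	82.14	0.00	0.00	0.00	44.63	0.00	43.19	35,485.73
MYO-6	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	2706.33
MYO-7	0.00	0.00	0.00	0.00	0.00	0.00	0.00	0.00	1805.60
MYO-8	3.83	960.47	8.14	0.00	0.00	0.00	0.00	0.00	0.00
NGF-1	2021.69	761.53	5039.75	2527.51	2023.71	1592.10	2240.15	2459.36	2108.54
NUC-1	779.38	366.04	1526.31	945.96	368.05	610.32	960.93	1068.46	502.67
PDE-1	445.18	229.67	691.74	312.13	236.13	209.66	277.73	208.12	249.61
Pla2gA1	25,306.99	39,764.45	61.41	46.36	2.19	4.48	50,036.23	0.00	0.61
Pla2gB1	3.44	7.16	29,405.58	14.34	1.43	37,548.76	46,634.43	51,949.04	31,992.11
Pla2gK	0.00	0.30	1793.61	3.04	0.00	1356.66	2971.25	1123.48	807.59
Pla2gA2-MTXA	274,390.23	80,733.96	102,588.14	199,107.20	102,677.33	4.93	65.65	0.00	0.00
Pla2gB2-MTXB	133,822.75	43,410.96	48,028.34	138,470.84	42,571.19	3.73	30.28	0.00	0.00
PLA2-6	21,306.42	22.86	106,639.29	90,911.79	51,893.58	60,760.91	56,428.98	129,974.00	93,064.76
PLB-1	837.02	189.30	1170.66	1059.23	597.70	509.37	745.22	346.61	182.83
SVMPII-1	0.00	0.84	0.60	122.86	3.30	23,801.48	32,375.22	24,762.53	24,369.30
SVMPIII-1	0.00	1.20	1.83	262.28	9.58	58,107.40	69,839.79	69,573.48	39,410.80
SVMPIII-2	8.60	3074.27	61.30	2524.10	479.43	3581.65	14,465.14	2364.36	4089.81
SVMPIII-3	0.01	0.79	1.32	206.34	6.17	6920.71	8968.12	7129.26	6456.84
SVMPIII-4	1497.61	1018.71	4893.89	2711.96	276.26	3637.08	4729.55	5060.59	2488.36
SVMPIII-5	6.65	4.39	4.51	2.02	0.00	1293.10	2689.88	3646.35	1942.60
SVMPIII-6	19.52	12.50	6.89	9.20	2.20	274.19	3250.08	2739.21	663.84
SVMPIII-7	0.02	0.17	0.57	16.36	0.53	643.82	2557.44	2534.21	994.18
SVMPIII-8	0.00	0.00	0.00	0.07	0.00	44.33	50.02	4977.26	25.70
SVMPIII-9	0.00	0.00	0.00	0.07	0.00	279.91	2000.74	1017.78	1092.48
SVMPIII-10	0.00	0.01	0.00	0.19	0.00	181.26	751.33	220.24	404.67
SVSP-1	25,158.51	15,910.07	30,344.55	17,038.01	10,432.56	21,732.91	32,652.46	20,711.71	26,686.11
SVSP-2	42,979.80	20,190.56	35,325.26	21,389.97	14,037.74	16,208.71	10,861.87	6624.20	6521.70
SVSP-3	24,402.09	7206.88	34,812.15	9121.20	3774.14	19,942.19	20,070.68	20,385.25	15,388.82
SVSP-4	29,001.28	5094.40	18,056.16	9305.84	1916.43	8654.88	9431.62	7042.42	8412.05
SVSP-5	37,090.47	5414.68	21,446.17	8874.54	1346.38	1863.68	5619.86	2373.32	3563.03
SVSP-6	11,830.88	7170.10	15,765.87	9603.42	4485.31	8500.16	12,274.97	6642.73	10,481.74
SVSP-7	7289.06	2382.92	5895.10	3081.90	1513.33	4024.78	2685.70	1659.02	1379.27
SVSP-8	4813.04	2087.12	5900.27	2021.75	407.33	2169.99	2985.67	1994.54	1945.35
SVSP-9	4048.20	724.15	1391.55	1288.30	1231.13	3097.60	3252.51	2154.34	3169.89
SVSP-10	4038.45	1189.72	4293.59	1766.03	84.61	1208.22	2752.40	2430.80	2459.42
SVSP-11	5777.06	1464.77	2503.34	1599.56	962.33	2311.84	3050.76	478.40	1664.01
SVSP-12	3674.93	1456.06	3014.74	2310.02	565.32	2209.80	1897.49	1761.75	1281.51
SVSP-13	3238.56	798.05	3159.21	1118.98	287.65	1467.22	709.22	982.38	1198.93
SVSP-14	1558.37	620.40	1082.12	667.47	38.63	762.05	289.19	599.21	693.61
VEGF-1	4255.45	10,557.63	14,271.01	11,732.75	7493.65	20,763.31	9620.66	12,596.93	10,796.52
VEGF-2	134.91	18.84	82.27	95.20	3.90	96.12	72.87	313.81	91.89
Vespryn-1	4976.55	718.69	3827.06	1024.92	1089.92	2106.99	2068.47	922.31	582.28
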
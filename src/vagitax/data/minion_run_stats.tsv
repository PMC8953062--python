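sample	region	pass_reads	pass_min_bp	pass_avg_bp	pass_max_bp	filtered_reads	printed_retention_pct	filtered_avg_bp
1_lavage	V1-9	115957	128	1434.3	4377	91449	78.9	1633.5
1_swab	V1-9	63547	155	1078.0	4193	31462	49.5	1619.3
2_lavage	V1-9	33721	158	1507.2	4486	28718	85.2	1607.0
2_swab	V1-9	53584	145	1203.6	3746	33294	62.1	1613.6
3_lavage	V1-9	28071	154	1396.3	4875	20958	74.7	1613.8
3_swab	V1-9	23053	162	1521.0	3990	20073	87.1	1614.5
4_lavage	V1-9	30603	155	1502.9	4977	25756	84.2	1639.5
4_swab	V1-9	37597	161	1103.2	3383	19588	52.1	1644.9
5_lavage	V1-9	15836	147	1346.1	3393	10688	67.5	1632.8
6_lavage	V1-9	38020	144	1517.2	3787	32255	84.8	1642.4
7_lavage	V1-9	61432	158	1218.8	5035	37018	60.3	1631.4
8_lavage	V1-9	52071	111	1257.5	3344	33906	65.1	1603.2
9_lavage	V1-9	119745	125	1530.5	4664	103212	86.2	1649.4
10_lavage	V1-9	102333	150	1496.5	4980	84028	82.1	1650.2
11_lavage	V1-9	61756	121	1541.3	3519	54116	87.6	1647.8
12_lavage	V1-9	101755	120	1433.9	4759	77756	76.4	1635.8
13_lavage	V1-9	71041	134	1437.5	4828	56601	79.7	1599.2
14_lavage	V1-9	42629	159	1367.7	4981	31447	73.8	1629.0
15_lavage	V1-9	52908	172	1452.9	3333	42910	81.1	1630.4
16_lavage	V1-9	52230	153	1480.3	4345	43549	83.4	1633.0
17_lavage	V1-9	38219	154	1478.3	3453	31757	83.1	1625.3
18_lavage	V1-9	28886	185	1464.7	3328	23816	82.4	1631.8
5_lavage	V3-4	74096	147	589.5	3038	29505	39.8	574.8
6_lavage	V3-4	83983	141	586.1	2099	33677	40.1	571.8
9_lavage	V3-4	49642	148	588.2	2275	21614	43.5	574.2
10_lavage	V3-4	65561	139	587.2	2873	28440	43.4	574.5
11_lavage	V3-4	98126	124	587.4	2568	40485	41.3	571.7
14_lavage	V3-4	79631	127	584.9	1849	35009	44.0	571.2
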
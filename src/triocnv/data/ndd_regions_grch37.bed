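1	146578857	147396590	1q21.1
3	195759925	197346552	3q29
7	72745827	74145433	7q11.23
15	22754734	28570518	15q11.2-13.1
15	31075790	32446853	15q13.3
16	28823088	29046734	16p11.2_distal
16	29650743	30195048	16p11.2_proximal
17	1247833	2588909	17p13.3
17	16811742	20216832	17p11.2
17	34816571	36215672	17q12
17	43706118	44165156	17q21.31
22	19024859	21469135	22q11.2
22	21920485	23652202	22q11.2_distal
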
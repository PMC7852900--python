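1	146099999	146200000	syn_blacklist_1_flank
3	197699999	197800000	syn_blacklist_3_flank
15	22299999	22400000	syn_blacklist_15_flank
16	28399999	28500000	syn_blacklist_16_flank
17	799999	900000	syn_blacklist_17_flank
22	18599999	18700000	syn_blacklist_22_flank
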
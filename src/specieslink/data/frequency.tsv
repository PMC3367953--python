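# Corpus-global species frequencies for tie-breaking.
# Synthetic rank-calibrated counts: ordering (human > rat > mouse > ...)
# is the datum; absolute counts are placeholders.
9606	15000
10116	10000
10090	9000
4932	4000
7227	3500
7955	2000
3702	1500
562	1200
83333	800
6239	700
9823	500
9913	400
9031	300
8355	200
10029	100
3701	50
59689	20
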
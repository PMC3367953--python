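# tax_id<TAB>parent_tax_id (minimal chains for the packaged lexicon)
83333	562
562	561
3702	3701
59689	3701
9606	9605
10090	10088
10116	10114
4932	4930
7227	7215
7955	7954
9823	9822
9913	9903
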
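budding	4932	0.061167
clinical	9606	0.065000
cohort	9606	0.068667
ferment	4932	0.068333
instar	7227	0.066000
knockout	10090	0.064500
littermates	10090	0.063167
metamorphosis	7227	0.064833
ommatidia	7227	0.069167
patients	9606	0.066333
sporulation	4932	0.070500
weaning	10090	0.072333
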
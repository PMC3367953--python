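# Cell-line name -> organism tax_id (cell-derived species cues)
hela	9606	cell-derived
hek293	9606	cell-derived
jurkat	9606	cell-derived
hepg2	9606	cell-derived
mcf-7	9606	cell-derived
3t3	10090	cell-derived
cho	10029	cell-derived
s2	7227	cell-derived
pc12	10116	cell-derived
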
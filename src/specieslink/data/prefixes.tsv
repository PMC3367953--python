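# Gene-symbol prefix letter -> tax_id (user-overridable)
h	9606
m	10090
r	10116
d	7227
z	7955
x	8355
y	4932
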
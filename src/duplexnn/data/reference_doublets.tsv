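label	dg_kcal_mol	reported_count
AA/TT	-0.838948	84
AC/TG	-1.394988	102
AG/TC	-1.323547	102
AT/TA	-0.375235	130
CA/GT	-1.406794	95
CC/GG	-1.698997	74
CG/GC	-0.967002	106
GA/CT	-0.938327	101
GC/CG	-0.711466	126
TA/AT	-0.144092	136
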
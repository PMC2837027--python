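label	dg_kcal_mol	reported_count
AAA/TTT	-0.844597	10
AAC/TTG	-1.841904	19
AAG/TTC	-1.201194	17
AAT/TTA	-0.991596	19
ACA/TGT	-1.121939	20
ACC/TGG	-1.793995	23
ACG/TGC	-1.615048	30
ACT/TGA	-0.781693	23
AGA/TCT	-1.103536	15
AGC/TCG	-1.528461	36
AGG/TCC	-1.323278	18
ATA/TAT	-0.562379	46
ATC/TAG	-1.157521	29
ATG/TAC	-1.263601	26
CAA/GTT	-0.988509	16
CAC/GTG	-2.088824	17
CAG/GTC	-1.625284	23
CCA/GGT	-1.568813	18
CCC/GGG	-2.396507	17
CCG/GGC	-1.888906	22
CGA/GCT	-1.668273	19
CGC/GCG	-2.195726	23
CTA/GAT	-0.871636	40
CTC/GAG	-1.198450	16
GAA/CTT	-1.317278	18
GAC/CTG	-1.498999	29
GCA/CGT	-1.454430	21
GCC/CGG	-1.973081	24
GGA/CCT	-1.696158	20
GTA/CAT	-1.158422	32
TAA/ATT	-0.519499	27
TCA/AGT	-1.042342	19
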
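chrom	pos	ref	alt	significance
ACO2	454	T	C	benign
OPA1	652	A	T	benign
TMEM126A	534	G	A	pathogenic
WFS1	373	A	C	pathogenic
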
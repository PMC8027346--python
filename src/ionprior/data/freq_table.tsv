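chrom	pos	ref	alt	maf
ACO2	454	T	C	0.0189
OPA1	652	A	T	0.057
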
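gene	chrom	strand	exons	cds_start	cds_end
OPA1	OPA1	+	121-328,394-450,501-966,1030-1201	121	1201
OPA3	OPA3	-	121-153,220-429	121	429
WFS1	WFS1	+	121-220,303-519,590-875	121	875
MFN2	MFN2	+	121-336,420-453,512-744	121	744
SPG7	SPG7	-	121-180,232-262,324-685	121	685
AFG3L2	AFG3L2	+	121-158,227-262,328-676	121	676
DNM1L	DNM1L	+	121-353,417-461,535-679	121	679
SSBP1	SSBP1	-	121-356,423-459	121	459
MIEF1	MIEF1	+	121-356,424-490	121	490
TMEM126A	TMEM126A	+	121-182,268-427,487-567	121	567
ACO2	ACO2	+	121-159,213-320,379-774	121	774
RTN4IP1	RTN4IP1	-	121-344,427-456,542-650	121	650
NDUFS2	NDUFS2	+	121-370,427-509	121	509
MCAT	MCAT	+	121-187,276-481	121	481
SLC25A46	SLC25A46	-	121-283,370-506,578-610	121	610
CAND1	CAND1	+	121-265,330-397	121	397
CAND2	CAND2	+	121-302,364-394	121	394
CAND3	CAND3	-	121-172,232-392	121	392
CAND4	CAND4	+	121-208,281-405	121	405
CAND5	CAND5	+	121-263,324-393	121	393
CAND6	CAND6	-	121-181,238-389	121	389
CAND7	CAND7	+	121-169,241-404	121	404
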
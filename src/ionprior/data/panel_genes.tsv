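symbol	modes	status	regions
OPA1	dominant,recessive	known	OPA1:111-338;OPA1:384-460;OPA1:491-976;OPA1:1020-1211
OPA3	dominant	known	OPA3:111-163;OPA3:210-439
WFS1	dominant,recessive	known	WFS1:111-230;WFS1:293-529;WFS1:580-885
MFN2	dominant	known	MFN2:111-346;MFN2:410-463;MFN2:502-754
SPG7	dominant,recessive	known	SPG7:111-190;SPG7:222-272;SPG7:314-695
AFG3L2	dominant	known	AFG3L2:111-168;AFG3L2:217-272;AFG3L2:318-686
DNM1L	dominant	known	DNM1L:111-363;DNM1L:407-471;DNM1L:525-689
SSBP1	dominant	known	SSBP1:111-366;SSBP1:413-469
MIEF1	dominant	known	MIEF1:111-366;MIEF1:414-500
TMEM126A	recessive	known	TMEM126A:111-192;TMEM126A:258-437;TMEM126A:477-577
ACO2	dominant,recessive	known	ACO2:111-169;ACO2:203-330;ACO2:369-784
RTN4IP1	recessive	known	RTN4IP1:111-354;RTN4IP1:417-466;RTN4IP1:532-660
NDUFS2	recessive	known	NDUFS2:111-380;NDUFS2:417-519
MCAT	recessive	known	MCAT:111-197;MCAT:266-491
SLC25A46	recessive	known	SLC25A46:111-293;SLC25A46:360-516;SLC25A46:568-620
CAND1	dominant	candidate	CAND1:111-275;CAND1:320-407
CAND2	dominant	candidate	CAND2:111-312;CAND2:354-404
CAND3	dominant	candidate	CAND3:111-182;CAND3:222-402
CAND4	dominant	candidate	CAND4:111-218;CAND4:271-415
CAND5	dominant	candidate	CAND5:111-273;CAND5:314-403
CAND6	dominant	candidate	CAND6:111-191;CAND6:228-399
CAND7	dominant	candidate	CAND7:111-179;CAND7:231-414
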
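domain	aa_start	aa_end
N-terminal	1	59
GTPase	60	160
central_dynamin	161	250
GED	251	290
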
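sample_id	location	phenotype	sex	q	Q
EGM18_2385	Boysen Reservoir	Sauger	F	0.143	0.286
EGM18_2522	Boysen Reservoir	Walleye	F	0.884	0.231
EGM18_2529	Boysen Reservoir	Walleye	F	0.550	0.899
EGM18_2550	Boysen Reservoir	Walleye	F	0.801	0.398
EGM18_2562	Boysen Reservoir	Walleye	M	0.297	0.593
EGM18_0187	Middle Bighorn	Walleye	M	0.885	0.230
EGM18_2663	Bighorn Lake	Sauger	unknown	0.111	0.222
EGM18_2684	Upper Bighorn	Sauger	unknown	0.102	0.203
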
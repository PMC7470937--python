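pair_name	1R 3H	R?	1H 3H	1 3H	No R?
TT_mWW_(23)(32)	52	8	6	0	0
TT_fWW_(23)(34)	6	0	0	0	0
TT_mWW_(34)(43)	57	1	0	1	0
TT_fWH_(34)(45)	1	0	0	0	0
TT_fWS_(21)(32)	NA	NA	4	0	1
TT_mSS_(12)(21)	NA	NA	5	0	0
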
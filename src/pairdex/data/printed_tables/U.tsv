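pair_name	1R 3H	R?	1H 3H	No R?
UU_mWW_(23)(32)	17	1	1	0
UU_fWW_(23)(34)	3	1	0	0
UU_mWW_(34)(43)	25	0	1	0
UU_fWH_(34)(45)	53	7	0	0
UU_mHH_(45)(54)	9	0	0	0
UU_mHS_(41)(52)	NA	NA	1	0
UU_mSS_(12)(21)	NA	NA	1	0
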
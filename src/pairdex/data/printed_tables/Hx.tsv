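pair_name	1H 3 7 9R	R?	1H 3 7 9H	No R?
HxHx_mWW_(16)(61)	0	0	1	0
HxHx_fWH_(17)(26)	7	0	0	2
HxHx_fWS_(13)(62)	1	0	0	0
HxHx_fHS_(68)(79)	NA	NA	1	0
HxHx_mSS_(23)(32)	1	0	1	0
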
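pair_name	1H 3 7 9R	1H 3 7H 9R	1 3H 7H 9R	1H 3 7 9R 1H 3 7H 9R	R?	1H 3 7 9H	1H 3 7H 9H	1H 3 7H 9	1H 3 7 9H 1H 3 7H 9H	No R?
GG_mWW_(16)(61)	1	1	-	0	0	0	0	0	0	0
GG_mWH_(16)(27)	11	-	-	0	0	0	-	-	0	0
GG_fWH_(16)(67)	-	0	-	1	0	-	0	0	0	0
GG_fWH_(26)(17)(68)	43	-	1	1	2	1	-	-	0	1
GG_mHH_(67)(76)	-	0	0	-	0	-	5	1	-	1
GG_mSS_(23)(32)	15	4	-	0	3	0	10	0	1	0
GG_mSS_(39)(93)	NA	NA	NA	NA	NA	1	0	-	0	0
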
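pair_name	1R 3	1R 3H	1R 3 1R 3H	R?	1H 3	1H 3H	1H 3 1H 3H	No R?
CC_mWW_(23)(32)	-	1	-	0	-	1	-	0
CC_mWW_(24)(33)(42)	3	-	15	4	3	-	36	1
CC_mWW_(34)(43)	24	-	-	0	0	-	-	0
CC_fWH_(24)(35)	8	0	1	0	0	-	0	0
CC_mWH_(25)(34)	0	-	1	0	0	-	0	0
CC_fWS_(26)(31)(42)	NA	NA	NA	NA	3	-	0	0
CC_mSS_(12)(21)	NA	NA	NA	NA	5	10	2	1
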
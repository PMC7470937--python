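pair_name	1 3 7 9R	1H 3 7 9R	R?	1 3 7 9H	1H 3 7 9H	1 3H 7H 9	1H 3 7H 9H	1H 3 7H 9	1 3 7H 9	1 3 7 9H 1H 3 7 9H	1 3 7H 9 1H 3 7 9H	No R?
AA_mWW_(12)(21)	13	-	2	1	-	0	-	-	0	-	-	0
AA_fWW_(16)(21)	1	-	0	0	-	0	-	-	0	-	-	0
AA_mWW_(16)(61)	32	-	4	4	-	0	-	-	3	-	-	0
AA_fWH_(18)(27)	2	-	0	1	-	-	-	-	-	0	0	0
AA_fWH_(16)(67)	98	-	7	1	-	-	-	-	-	0	0	0
AA_fWS_(19)(63)	NA	NA	NA	-	-	-	-	2	-	-	1	0
AA_mHH_(67)(76)	27	23	12	2	19	-	-	-	-	1	-	2
AA_fHH_(67)(78)	2	0	0	0	0	-	-	-	-	0	-	0
AA_mHH_(78)(87)	11	0	1	2	1	-	-	-	-	0	-	0
AA_fHS_(63)(72)	1	0	0	1	0	-	-	-	-	0	0	0
AA_mHS_(63)(79)	NA	NA	NA	0	1	-	-	-	-	0	0	0
AA_mHS_(72)(83)	5	1	0	0	3	-	-	-	-	0	0	0
AA_fHS_(79)(83)	NA	NA	NA	0	1	-	-	-	-	0	0	0
AA_mSS_(23)(32)	5	2	3	0	3	-	1	0	0	0	0	1
AA_mSS_(39)(93)	NA	NA	NA	6	10	1	3	-	-	1	-	1
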
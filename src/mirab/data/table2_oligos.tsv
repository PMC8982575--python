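name	target	shrnamir	species	designed_by	top	bottom
HDAC1_sh1_Human	HDAC1	sh1	Human	SplashRNA	GATCCGAGGTTAGGTTGCTTCAATCTAATAGTGAAGCCACAGATGTATTAGATTGAAGCAACCTAACCGTGGGCC	CACGGTTAGGTTGCTTCAATCTAATACATCTGTGGCTTCACTATTAGATTGAAGCAACCTAACCTCG
HDAC1_sh2_Human	HDAC1	sh2	Human	SplashRNA	GATCCGACACAGCGATGACTACATTAAATAGTGAAGCCACAGATGTATTTAATGTAGTCATCGCTGTGGTGGGCC	CACCACAGCGATGACTACATTAAATACATCTGTGGCTTCACTATTTAATGTAGTCATCGCTGTGTCG
SMAR4A_sh1_Human	SMAR4A	sh1	Human	SplashRNA	GATCCGATGGATGTCAAACAGTAATAAATAGTGAAGCCACAGATGTATTTATTACTGTTTGACATCCAGTGGGCC	CACTGGATGTCAAACAGTAATAAATACATCTGTGGCTTCACTATTTATTACTGTTTGACATCCATCG
SMAR4A_sh2_Human	SMAR4A	sh2	Human	SplashRNA	GATCCGACCGTGGACTTCAAGAAGATAATAGTGAAGCCACAGATGTATTATCTTCTTGAAGTCCACGGGTGGGCC	CACCCGTGGACTTCAAGAAGATAATACATCTGTGGCTTCACTATTATCTTCTTGAAGTCCACGGTCG
MTA1_sh1_Human	MTA1	sh1	Human	SplashRNA	GATCCGCTCAAGTAATTTTCATATTAAATAGTGAAGCCACAGATGTATTTAATATGAAAATTACTTGAATGGGCC	CATTCAAGTAATTTTCATATTAAATACATCTGTGGCTTCACTATTTAATATGAAAATTACTTGAGCG
MTA1_sh2_Human	MTA1	sh2	Human	SplashRNA	GATCCGAAAGGTGCCATTTTAAATTTTATAGTGAAGCCACAGATGTATAAAATTTAAAATGGCACCTTCTGGGCC	CAGAAGGTGCCATTTTAAATTTTATACATCTGTGGCTTCACTATAAAATTTAAAATGGCACCTTTCG
MTA2_sh1_Human	MTA2	sh1	Human	SplashRNA	GATCCGACAGCATAGTCCAGTTTTATTATAGTGAAGCCACAGATGTATAATAAAACTGGACTATGCTGGTGGGCC	CACCAGCATAGTCCAGTTTTATTATACATCTGTGGCTTCACTATAATAAAACTGGACTATGCTGTCG
MTA2_sh2_Human	MTA2	sh2	Human	SplashRNA	GATCCGCACGCCAGTTCTCAGAAATAAATAGTGAAGCCACAGATGTATTTATTTCTGAGAACTGGCGTATGGGCC	CATACGCCAGTTCTCAGAAATAAATACATCTGTGGCTTCACTATTTATTTCTGAGAACTGGCGTGCG
FAS_sh1_Human	FAS	sh1	Human	SplashRNA	GATCCGCAGTGTTTGAAAAGATTCTTAATAGTGAAGCCACAGATGTATTAAGAATCTTTTCAAACACTATGGGCC	CATAGTGTTTGAAAAGATTCTTAATACATCTGTGGCTTCACTATTAAGAATCTTTTCAAACACTGCG
FAS_sh2_Human	FAS	sh2	Human	SplashRNA	GATCCGATCCAAGGATGTTTAAAATCTATAGTGAAGCCACAGATGTATAGATTTTAAACATCCTTGGAGTGGGCC	CACTCCAAGGATGTTTAAAATCTATACATCTGTGGCTTCACTATAGATTTTAAACATCCTTGGATCG
CD4_sh1_Human	CD4	sh1	Human	SplashRNA	GATCCGACCTGATCATCAAGAATCTTAATAGTGAAGCCACAGATGTATTAAGATTCTTGATGATCAGGGTGGGCC	CACCCTGATCATCAAGAATCTTAATACATCTGTGGCTTCACTATTAAGATTCTTGATGATCAGGTCG
FAS_sh1_Mouse	FAS	sh1	Mouse	SplashRNA	GATCCGAACAGTTAAGAGTTCATACTCATAGTGAAGCCACAGATGTATGAGTATGAACTCTTAACTGTGTGGGCC	CACACAGTTAAGAGTTCATACTCATACATCTGTGGCTTCACTATGAGTATGAACTCTTAACTGTTCG
FAS_sh2_Mouse	FAS	sh2	Mouse	SplashRNA	GATCCGACGGGTTCGTGAAACTGATAAATAGTGAAGCCACAGATGTATTTATCAGTTTCACGAACCCGCTGGGCC	CAGCGGGTTCGTGAAACTGATAAATACATCTGTGGCTTCACTATTTATCAGTTTCACGAACCCGTCG
Tbx21_sh1_Mouse	Tbx21	sh1	Mouse	shERWOOD	GATCCGCCACACACGTCTTTACTTTCCATAGTGAAGCCACAGATGTATGGAAAGTAAAGACGTGTGTGTTGGGCC	CAACACACACGTCTTTACTTTCCATACATCTGTGGCTTCACTATGGAAAGTAAAGACGTGTGTGGCG
CD4_sh1_Mouse	CD4	sh1	Mouse	shERWOOD	GATCCGAGCATGGGAGAAAGGATCGTTTTAGTGAAGCCACAGATGTAAAACGATCCTTTCTCCCATGCCTGGGCC	CAGGCATGGGAGAAAGGATCGTTTTACATCTGTGGCTTCACTAAAACGATCCTTTCTCCCATGCTCG
CD4_sh1_Mouse	CD4	sh1	Mouse	SplashRNA	GATCCGCACAGCATATCTTAATTCATAATAGTGAAGCCACAGATGTATTATGAATTAAGATATGCTGTTTGGGCC	CAAACAGCATATCTTAATTCATAATACATCTGTGGCTTCACTATTATGAATTAAGATATGCTGTGCG
CD19_sh1_Mouse	CD19	sh1	Mouse	SplashRNA	GATCCGACAGTCCTATGAAGATATGAGATAGTGAAGCCACAGATGTATCTCATATCTTCATAGGACTGGTGGGCC	CACCAGTCCTATGAAGATATGAGATACATCTGTGGCTTCACTATCTCATATCTTCATAGGACTGTCG
CD127_sh1_Mouse	CD127	sh1	Mouse	SplashRNA	GATCCGCGGGTAAGTTATTCAAATTCAATAGTGAAGCCACAGATGTATTGAATTTGAATAACTTACCCATGGGCC	CATGGGTAAGTTATTCAAATTCAATACATCTGTGGCTTCACTATTGAATTTGAATAACTTACCCGCG
CD127_sh2_Mouse	CD127	sh2	Mouse	SplashRNA	GATCCGCCCATGTCTAGTTTTTACCAAATAGTGAAGCCACAGATGTATTTGGTAAAAACTAGACATGGTTGGGCC	CAACCATGTCTAGTTTTTACCAAATACATCTGTGGCTTCACTATTTGGTAAAAACTAGACATGGGCG
CD44_sh1_Mouse	CD44	sh1	Mouse	SplashRNA	GATCCGCCAGGTTTGAGTTTATATCAAATAGTGAAGCCACAGATGTATTTGATATAAACTCAAACCTGATGGGCC	CATCAGGTTTGAGTTTATATCAAATACATCTGTGGCTTCACTATTTGATATAAACTCAAACCTGGCG
CD44_sh2_Mouse	CD44	sh2	Mouse	SplashRNA	GATCCGAAGGGTATAAATTGATTCATAATAGTGAAGCCACAGATGTATTATGAATCAATTTATACCCTGTGGGCC	CACAGGGTATAAATTGATTCATAATACATCTGTGGCTTCACTATTATGAATCAATTTATACCCTTCG
CD90_sh1_Mouse	CD90	sh1	Mouse	SplashRNA	GATCCGAAGGGCTGCTTCTGATTATTTATAGTGAAGCCACAGATGTATAAATAATCAGAAGCAGCCCTGTGGGCC	CACAGGGCTGCTTCTGATTATTTATACATCTGTGGCTTCACTATAAATAATCAGAAGCAGCCCTTCG
CD90_sh2_Mouse	CD90	sh2	Mouse	SplashRNA	GATCCGCGCTGTCATTTTGTACTCTGTATAGTGAAGCCACAGATGTATACAGAGTACAAAATGACAGCTTGGGCC	CAAGCTGTCATTTTGTACTCTGTATACATCTGTGGCTTCACTATACAGAGTACAAAATGACAGCGCG
CD8_sh1_Mouse	CD8	sh1	Mouse	SplashRNA	GATCCGCCAGTTCCTTTTTCTTTATGAATAGTGAAGCCACAGATGTATTCATAAAGAAAAAGGAACTGTTGGGCC	CAACAGTTCCTTTTTCTTTATGAATACATCTGTGGCTTCACTATTCATAAAGAAAAAGGAACTGGCG
CD8_sh2_Mouse	CD8	sh2	Mouse	SplashRNA	GATCCGACTGTAGTAGAATCCAATTAAATAGTGAAGCCACAGATGTATTTAATTGGATTCTACTACAGCTGGGCC	CAGCTGTAGTAGAATCCAATTAAATACATCTGTGGCTTCACTATTTAATTGGATTCTACTACAGTCG
Pten_1524_Mouse	Pten	1524	Mouse	SplashRNA	GATCCGACAGCTAAAGGTGAAGATATATTAGTGAAGCCACAGATGTAATATATCTTCACCTTTAGCTGGTGGGCC	CACCAGCTAAAGGTGAAGATATATTACATCTGTGGCTTCACTAATATATCTTCACCTTTAGCTGTCG
Pten_932_Mouse	Pten	932	Mouse	SplashRNA	GATCCGCCGACTTAGACTTGACCTATATTAGTGAAGCCACAGATGTAATATAGGTCAAGTCTAAGTCGATGGGCC	CATCGACTTAGACTTGACCTATATTACATCTGTGGCTTCACTAATATAGGTCAAGTCTAAGTCGGCG
GFP_sh1_N-A	GFP	sh1	N/A	SplashRNA	GATCCGAATGGACGAGCTGTACAAGTAATAGTGAAGCCACAGATGTATTACTTGTACAGCTCGTCCATGTGGGCC	CACATGGACGAGCTGTACAAGTAATACATCTGTGGCTTCACTATTACTTGTACAGCTCGTCCATTCG
GFP_sh2_N-A	GFP	sh2	N/A	SplashRNA	GATCCGAACAAGCTGGAGTACAACTACATAGTGAAGCCACAGATGTATGTAGTTGTACTCCAGCTTGTGTGGGCC	CACACAAGCTGGAGTACAACTACATACATCTGTGGCTTCACTATGTAGTTGTACTCCAGCTTGTTCG
GFP_sh3_N-A	GFP	sh3	N/A	SplashRNA	GATCCGCCAAGCAGAAGAACGGCATCAATAGTGAAGCCACAGATGTATTGATGCCGTTCTTCTGCTTGTTGGGCC	CAACAAGCAGAAGAACGGCATCAATACATCTGTGGCTTCACTATTGATGCCGTTCTTCTGCTTGGCG
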
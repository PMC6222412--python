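name	sequence	expected_size	species
CM F2	GGCCCCAAACAGTGTATCTAC	339	C_militaris
CM R2	CCGGTGCGAGTTGGCGTACTA	339	C_militaris
CM F3	CAACCCTTTGTGAACATACCT	102	C_militaris
CM R3	GTAGATACACTGTTTGGGGCC	102	C_militaris
CP F2	GACCCCAAACTCTGTTTCTAG	244	C_pruinosa
CP R2	CCCCGCGAGGAGGGGTCGAGT	244	C_pruinosa
CP F1	ACTCGACCCCTCCTCGCGGGG	116	C_pruinosa
CP R1	GTCCCGGTGCGACTGGTGTG	116	C_pruinosa
IC F1	ACGCAACCCTGTATCCATCAGT	337	I_cicadae
IC R1	TTCCCGGTGCGACTGGTTGT	337	I_cicadae
IC F3	ACCCTTCTGTGAACCTACGCATC	137	I_cicadae
IC R3	GATTCAGCGAGACTGATGGAT	137	I_cicadae
IT F4	CCTTCTGTGAACCTACCCATA	132	I_tenuipes
IT R3	GAGCGGCTCACAGATACAGG	132	I_tenuipes
IT F3	CCATACTTGCTTCGGCGGACC	107	I_tenuipes
IT R2	GCTCACAGATACAGGGTTGC	107	I_tenuipes
OS F1	AGCGTCATCTCAACCCTCGAG	200	O_sinensis
OS R2	TGATCCGAGGTCAACTGGAGG	200	O_sinensis
OS F3	GAACACCACAGCAGTTGCCT	117	O_sinensis
OS R3	GCTTCTTGACTGAGAGATGCC	117	O_sinensis
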
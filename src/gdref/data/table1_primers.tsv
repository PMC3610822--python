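name	sequence	target_gene	target_name
SCO5898F	cggagaacaagggcaagc	SCO5898	redF
SCO5898R	cagggggatggcgaag	SCO5898	redF
SCO7014F	gctcaggtggcgaagaag	SCO7014	SCO7014
SCO7014R	gcaactcgggcaggac	SCO7014	SCO7014
SCO5085F	gcggctttttggaatgc	SCO5085	actII4
SCO5085R	gcagggtctcgttcagc	SCO5085	actII4
SCO6992F	cggaccttccacaacatcc	SCO6992	absR1
SCO6992R	tcgggctccagtatcagg	SCO6992	absR1
SCO5582F	ctcggctcctacatcctctc	SCO5582	nsdA
SCO5582R	ctccatcgcgtacagcatc	SCO5582	nsdA
SCO3878F	gggcgtgctcatcctg	SCO3878	SCO3878
SCO3878R	gcttcgtggaggtcgtg	SCO3878	SCO3878
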
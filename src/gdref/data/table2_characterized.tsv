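function	gene_id	description	mc_24	mc_48	mc_72
Krebs cycle and energy metabolism	SCO0924	Cytochrome B subunit	0.6	-3.5	-3.3
Krebs cycle and energy metabolism	SCO3945	Cytochrome oxidase subunit I, CydA	-1.8	-4.6	-4.2
Krebs cycle and energy metabolism	SCO3946	Cytochrome oxidase subunit II, CydB	-1	-3.7	-3.5
Glycolysis and glyconeogenesis	SCO1947	Glyceraldehyde-3-phosphate dehydrogenase	0.6	-1.9	-2
Glycolysis and glyconeogenesis	SCO7511	Glyceraldehyde-3-phosphate dehydrogenase	-0.9	-2.7	-2.7
Ribosomal	SCO3909	RplI	-1.2	-1.3	-1.2
Hydrophobic covers - Sporulation	SCO0409	SapA	1	1.5	2.7
Hydrophobic covers - Sporulation	SCO1674	ChpC	3.2	4.4	4.4
Hydrophobic covers - Sporulation	SCO1675	ChpH	5.4	5.2	4.7
Hydrophobic covers - Sporulation	SCO1800	ChpE	5.7	5.3	5.3
Hydrophobic covers - Sporulation	SCO2705	ChpF	0.8	1.6	1.4
Hydrophobic covers - Sporulation	SCO2717	ChpD	3.7	5.5	5.6
Hydrophobic covers - Sporulation	SCO2718	RdlA	1.1	7	7.4
Hydrophobic covers - Sporulation	SCO3323	BldN	4.6	4.3	4.2
Hydrophobic covers - Sporulation	SCO3579	WblA	2.9	3.4	3.5
Hydrophobic covers - Sporulation	SCO4091	BldC	1	0.9	1.4
Hydrophobic covers - Sporulation	SCO4543	WhiJ	-1	-1.3	-1.4
Hydrophobic covers - Sporulation	SCO4768	BldM	2.8	3	3.5
Hydrophobic covers - Sporulation	SCO5113	BldkB	1.5	0.9	0.6
Hydrophobic covers - Sporulation	SCO5190	WblC	-1.7	2	3.2
Hydrophobic covers - Sporulation	SCO5240	WblE	2.2	1.4	2
Hydrophobic covers - Sporulation	SCO5316	WhiE	0.8	1	3.9
Hydrophobic covers - Sporulation	SCO5319	WhiE protein II	1.7	0.9	2.7
Hydrophobic covers - Sporulation	SCO5582	NdsA	2.4	3.2	3.1
Hydrophobic covers - Sporulation	SCO5621	WhiG	0.4	0.9	0.6
Hydrophobic covers - Sporulation	SCO5723	BldB	0.8	0.9	1
Hydrophobic covers - Sporulation	SCO5819	WhiH	1.3	2	1.8
Hydrophobic covers - Sporulation	SCO6681	RamC	0.8	2.4	1.1
Hydrophobic covers - Sporulation	SCO6682	RamS	3.7	5.3	4.6
Hydrophobic covers - Sporulation	SCO6683	RamA	0.9	2	1
Hydrophobic covers - Sporulation	SCO6992	AbsR1	1.5	4.7	5.8
Secondary metabolite synthesis	SCO3227	Aminotransferase	-0.6	-0.7	-0.8
Secondary metabolite synthesis	SCO3229	4-hydroxyphenylpyruvic acid dioxygenase	-0.4	-0.7	-0.9
Secondary metabolite synthesis	SCO3235	ABC transporter	-0.4	-0.8	-0.9
Secondary metabolite synthesis	SCO3242	Putative transferase	-0.7	-0.8	-0.9
Secondary metabolite synthesis	SCO3243	Myo-inositol phosphate synthase	-0.7	-0.6	-0.6
Secondary metabolite synthesis	SCO5077	ActVA	1.1	1.3	1.3
Secondary metabolite synthesis	SCO5085	ActII-4	1.4	2	2.6
Secondary metabolite synthesis	SCO5898	RedF	1.6	2.1	1.7
Secondary metabolite synthesis	SCO6073	GeoA, cyclase	2.2	1.2	0.3
Secondary metabolite synthesis	SCO6273	Type I polyketide synthase cpkC	-1	-1.4	-1.3
Secondary metabolite synthesis	SCO6274	Type I polyketide synthase cpkB	-1.7	-2.1	-1.9
Secondary metabolite synthesis	SCO6275	Type I polyketide synthase cpkA	-1.9	-2.1	-2.3
Secondary metabolite synthesis	SCO6276	Secreted monooxygenase	-0.9	-2.8	-2.3
Secondary metabolite synthesis	SCO6277	Epoxide hydrolase	-1.1	-2.7	-2.3
Secondary metabolite synthesis	SCO6278	Integral membrane transport protein	-1.1	-2.3	-1.9
Secondary metabolite synthesis	SCO6279	Diaminobutyrate-pyruvate aminotransferase	-0.9	-2.5	-1.9
Secondary metabolite synthesis	SCO6280	Putative transcriptional regulator	-0.5	-0.7	-0.7
Secondary metabolite synthesis	SCO6281	FAD-binding protein	-0.8	-0.9	-0.6
Secondary metabolite synthesis	SCO6286	Putative transcriptional repressor	1.6	1	1.8
Secondary metabolite synthesis	SCO6288	Putative transcriptional regulator	-0.6	-0.7	-0.4
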
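gene_id	description	mc_24	mc_48	mc_72
SCO0185	Geranylgeranyl pyrophosphate synthase	-0.8	-0.9	-1
SCO0186	Phytoene dehydrogenase	-1.2	-1.6	-1.6
SCO0187	Phytoene synthase	-0.7	-0.6	-0.5
SCO0188	Methylesterase	-1.3	-1.4	-1.3
SCO0189	Dehydrogenase	-0.8	-1.1	-1.2
SCO0190	Methyltransferase	-1.4	-2.3	-2.4
SCO0191	Lycopene cyclase	-1.2	-1.9	-2.1
SCO0381	Glycosyl transferase	2.4	3.5	3.6
SCO0382	Dehydrogenase	1.9	3.1	3.1
SCO0383	Hypothetical protein	2.9	4	3.8
SCO0384	Putative exopolysaccharide transport	1.8	2.8	2.6
SCO0385	Putative exopolysaccharide transport	1.8	2.8	2.7
SCO0386	Asparagine synthetase	1.2	2.3	2.2
SCO0387	Bi-domain-containing oxidoreductase	2	3.1	2.9
SCO0388	Hypothetical protein	0.8	1.7	1.5
SCO0389	Lipoprotein	1.4	2.8	2.7
SCO0390	Hypothetical protein	1.4	2.7	2.5
SCO0391	Transferase	1.2	2.6	2.3
SCO0392	Methyltransferase	2	2.9	2.9
SCO0393	Transferase	2.4	3.5	3.5
SCO0394	Hypothetical protein	2.4	3.3	3.2
SCO0395	Epimerase/dehydratase	2.7	3.4	3.2
SCO0396	Putative Peptidase	2.7	3.7	3.4
SCO0397	Hypothetical protein	1.2	2.1	1.7
SCO0398	Glycosyl transferase	1.8	2.6	2.2
SCO0399	Possible membrane protein	2.7	3.6	3.3
SCO0400	Epimerase	2.3	3.3	2.9
SCO0401	Glutamate-1-semialdehyde 2,1-aminomutase	1.5	2.4	2.2
SCO0490	Esterase	0.9	-1.2	-1.1
SCO0491	ABC transporter transmembrane protein	0.9	-0.4	-0.8
SCO0492	Peptide synthetase	1.2	-0.6	-1.1
SCO0493	ABC-transporter transmembrane protein	0.5	-0.8	-0.9
SCO0497	Iron-siderophore permease	0.8	-1.6	-1.8
SCO0498	Peptide monooxygenase	2	-1.4	-2.3
SCO0499	Methionyl-tRNA formyltransferase	1.4	-1	-1.6
SCO1267	Acyl carrier protein	-3.6	-3.4	-3.9
SCO2782	Pyridoxal-dependent decarboxylase	1.1	-3.7	-3.2
SCO5799	Aminotransferase	0.4	1.3	1.8
SCO5801	Hypothetical protein	0.8	1.8	1.3
SCO6424	Histidine kinase	-0.4	0.7	2.3
SCO6435	Hypothetical protein	-0.4	-0.6	-1.1
SCO6760	Phytoene synthase	0.5	0.4	0.4
SCO6762	Phytoene dehydrogenase	0.9	1.1	1.1
SCO6763	Polyprenyl synthatase	1	1	0.9
SCO6764	Squalene-hopene cyclase	1.4	0.7	0.5
SCO6766	Hypothetical protein	2.5	1.1	0.9
SCO6767	4-hydroxy-3-methylbut-2-en-1-yl diphosphate synthase	1.2	0.6	0.5
SCO6768	Probable transketolase	1.3	0.5	0.2
SCO6769	Aminotransferase	1.3	0.4	0.3
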
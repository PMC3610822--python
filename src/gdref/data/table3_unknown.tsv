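function	gene_id	description	mc_24	mc_48	mc_72
Sporulation	SCO2805	Putative sporulation protein	0.8	3.5	3.4
DNA/RNA replication	SCO5494	NAD-dependent DNA ligase LigA	-3.4	-2.5	-2.2
Transcriptional Regulators	SCO0944	Predicted transmembrane transcriptional regulator	1	3.2	3
Transcriptional Regulators	SCO5656	Transcriptional regulatory protein	-4.1	-4.3	-3.8
Transcriptional Regulators	SCO4640	TetR family transcriptional regulator	-4.5	-4.5	-4.2
Transcriptional Regulators	SCO7014	LacI family transcriptional regulator	-2.5	-3	-4.5
Transcriptional Regulators	SCO4032	MarR regulatory protein	-4.3	-5.1	-5.4
Transcriptional Regulators	SCO4336	MarR-family protein	-2.1	-3.3	-2.6
Transcriptional Regulators	SCO2730	TetR-family transcriptional regulator	-3	-2.4	-1.9
Other Regulatory Proteins	SCO5351	Regulatory protein	0.8	2.8	3.3
Other Regulatory Proteins	SCO3134	Two-component system response regulator	0.9	3	3.2
Other Regulatory Proteins	SCO1629	rarB homologue	3.4	3.1	2.8
Unknown	SCO5447	Neutral zinc metalloprotease	0.4	3.1	1.2
Unknown	SCO4440	Hypothetical protein	1.6	4.6	4.9
Unknown	SCO0682	Hypothetical protein	4.3	4.5	4.7
Unknown	SCO1756	Hypothetical protein	1.8	3.9	4.7
Unknown	SCO2492	Hypothetical protein	2.5	4.8	4.5
Unknown	SCO0930	Putative lipoprotein	0.9	4.4	4.3
Unknown	SCO0683	Hypothetical protein	3.8	4.4	4.2
Unknown	SCO6165	Putative dnaK suppressor	-1.2	-0.9	4.2
Unknown	SCO3328	Hypothetical protein	2.1	3.7	4.2
Unknown	SCO6652	Hypothetical protein	0.8	4.3	4.1
Unknown	SCO7251	Hypothetical protein	4.1	4.4	4.1
Unknown	SCO1474	Hypothetical protein	2.8	3.4	4
Unknown	SCO1029	Hypothetical protein	2	3.8	3.9
Unknown	SCO2819	Hypothetical protein	2.2	3.7	3.8
Unknown	SCO0644	Possible membrane protein	0.6	4	3.9
Unknown	SCO4335	Hypothetical protein	2.1	3.3	3.6
Unknown	SCO5175	Hypothetical protein	2.4	3.8	3.5
Unknown	SCO5174	Transferase	2.2	3.5	3.5
Unknown	SCO3324	Hypothetical protein	2.7	3.1	3.5
Unknown	SCO5191	Hypothetical protein	-2	2.1	3.3
Unknown	SCO0684	Hypothetical protein	2.7	3.4	3.3
Unknown	SCO7253	Hypothetical protein	1.2	3.1	3.2
Unknown	SCO5834	Hypothetical protein membrane spanning	1.5	3.1	3.2
Unknown	SCO2302	Hypothetical protein	2.6	3.1	3.2
Unknown	SCO4173	Hypothetical protein	2.5	2.8	3.1
Unknown	SCO5177	Hypothetical protein	2.6	3.3	3
Unknown	SCO1860	Hypothetical protein	2.7	3.4	3
Unknown	SCO5655	Hypothetical protein	-4	-4.4	-4.3
Unknown	SCO5484	Small hydrophobic membrane protein	-4.7	-5.2	-5.6
Unknown	SCO1823	Hypothetical protein	1.2	3.9	2.1
Unknown	SCO0932	Hypothetical protein	1.8	3.5	2.8
Unknown	SCO6795	Hypothetical protein	2.5	3.4	2.5
Unknown	SCO5249	Nucleotide-binding protein	2.9	3.2	2.4
Unknown	SCO6797	ATP/GTP binding protein	2.2	3	2.2
Unknown	SCO2205	Hypothetical protein	-3.5	-3.6	-1.9
Unknown	SCO7471	Phenylacetate-CoA oxygenase PaaA	3.4	1.2	1.3
Unknown	SCO1105	Hypothetical protein	3.2	1.8	0.8
Unknown	SCO7472	Phenylacetate-CoA oxygenase PaaB	3.2	0.8	0.7
Unknown	SCO4793	Probable NPL/P60 family secreted protein	1.7	3.8	3.9
Unknown	SCO7453	Putative secreted protein	1.5	1.7	3.4
Unknown	SCO4677	Histidine kinase-like ATPase	4.2	4.4	4.1
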
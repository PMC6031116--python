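genome_id	environment	genome_size	gene_number	unannotated_genes	average_gene_size	total_coding	coding_density	cazy_genes	unduplicated_cazy
T_rhizospherense	Rhizosphere	1450269	1531	704	843.3	1280911	88	58	27
47_87_scnpilot	Wastewater	900471	918	376	896	822552	91	30	17
49_20_scnpilot	Wastewater	904897	933	362	891.5	831756	92	28	14
GW2011_GWC2_44_17	Aquifer	1038683	1093	482	860.3	939465	90	40	20
RAAC3_TM7	Aquifer	845464	921	355	835.5	769452	91	28	17
TM7x	Human_mouth	705138	711	241	919.2	653574	93	30	17
S_aalborgensis	Wastewater	1013781	1056	481	876.5	925533	91	30	17
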
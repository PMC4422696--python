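quantity	count	provenance
gwas_studies	16	results_text
gwas_studies	17	flowchart
proteomics_studies	17	results_text
proteomics_studies	18	flowchart
metabolomics_studies	18	results_text
metabolomics_studies	19	flowchart
genes	115	both
proteins	56	both
metabolites	227	both
metabolite_protein_pairs	1660	both
metabolite_proteins	840	both
risk_proteins	992	both
targets_with_projects	108	both
druggable_targets	35	both
known_antidiabetic_targets	5	both
known_target_drugs	22	results_text
known_target_drug_projects	27	flowchart
novel_targets	30	both
novel_target_drug_projects	167	both
therapeutic_targets	12	both
therapeutic_drugs	58	both
supported_drugs	9	results_text
drugs_data_no_link	11	results_text
drugs_no_data	38	results_text
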
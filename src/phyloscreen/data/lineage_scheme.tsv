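phylum	lineage	binary_group
Cyanophyta	PLANT_ALGAE	NOT_APPLICABLE
Phaeophyta	PLANT_ALGAE	NOT_APPLICABLE
Rhodophyta	PLANT_ALGAE	NOT_APPLICABLE
Chlorophyta	PLANT_ALGAE	NOT_APPLICABLE
Angiospermata	PLANT_ALGAE	NOT_APPLICABLE
Porifera	EARLY_METAZOAN	DEUTEROSTOME_INCL_ANCESTRAL
Cnidaria	EARLY_EUMETAZOAN	DEUTEROSTOME_INCL_ANCESTRAL
Echinodermata	DEUTEROSTOME	DEUTEROSTOME_INCL_ANCESTRAL
Chordata	DEUTEROSTOME	DEUTEROSTOME_INCL_ANCESTRAL
Bryozoa	NON_DEUTEROSTOME	NON_DEUTEROSTOME
Mollusca	NON_DEUTEROSTOME	NON_DEUTEROSTOME
Annelida	NON_DEUTEROSTOME	NON_DEUTEROSTOME
Crustacea	NON_DEUTEROSTOME	NON_DEUTEROSTOME
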
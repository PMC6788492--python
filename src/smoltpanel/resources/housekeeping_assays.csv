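assay_id,gene_symbol,gene_name,predicted_direction,functional_group,passed_efficiency,is_housekeeping
Coil-P84,Coil-P84,Coiled-coil domain-containing protein 84,,housekeeping,True,True
78d16.1,78d16.1,78d16.1 reference transcript,,housekeeping,True,True
MrpL40,MrpL40,39S mitochondrial ribosomal protein L40,,housekeeping,True,True
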
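respondent,round,question,code,dpsir_tag,vote
sector_I,2,value_tree_structure,,,agree
sector_II,2,value_tree_structure,,,agree
sector_III,2,value_tree_structure,,,agree
sector_IV,2,value_tree_structure,,,agree
sector_I,2,typical_case_definition,,,agree
sector_II,2,typical_case_definition,,,agree
sector_III,2,typical_case_definition,,,agree
sector_IV,2,typical_case_definition,,,agree
sector_I,2,keyword_categorization,,,agree
sector_II,2,keyword_categorization,,,agree
sector_III,2,keyword_categorization,,,agree
sector_IV,2,keyword_categorization,,,agree
sector_I,2,descriptor_levels,,,agree
sector_II,2,descriptor_levels,,,agree
sector_III,2,descriptor_levels,,,agree
sector_IV,2,descriptor_levels,,,agree
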
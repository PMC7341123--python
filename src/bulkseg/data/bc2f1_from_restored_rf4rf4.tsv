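population	parent_class	total	sterile	grade_V	grade_III_IV
BC2F1	fully_restored_rf4rf4	561	490	5	66
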
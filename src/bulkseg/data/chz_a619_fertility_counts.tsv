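population	environment	genotype	I	II	III	IV	V
F2	Chengdu	Rf4Rf4	0	0	4	1	322
F2	Chengdu	Rf4rf4	0	0	3	0	625
F2	Chengdu	rf4rf4	5	28	22	9	227
F2	Jinghong	Rf4Rf4	0	0	0	0	630
F2	Jinghong	Rf4rf4	0	0	2	0	1314
F2	Jinghong	rf4rf4	11	58	36	25	531
BC1F1	Chengdu	Rf4rf4	0	0	0	1	253
BC1F1	Chengdu	rf4rf4	45	97	34	13	31
BC1F1	Jinghong	Rf4rf4	0	0	0	0	130
BC1F1	Jinghong	rf4rf4	24	46	7	3	28
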
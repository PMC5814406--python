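# MitomiR evidence snapshot: which of the 16 liver-PNF miRNAs have been experimentally
# isolated from mitochondria (NGS, array, CLIP, RT-qPCR or functional data), plus the
# database-snapshot target counts (miRDB predicted targets; MitoMiner-recorded targets;
# MitoMiner targets with IMPI > 0.7). The count columns are display-only snapshot values
# from database versions current in 2017 and are never recomputed.
# Columns: mirna_id, is_mitomir (Y/N), mirdb_targets, mitominer_targets, impi_gt07_targets, evidence_refs
mirna_id	is_mitomir	mirdb_targets	mitominer_targets	impi_gt07_targets	evidence_refs
miR-107	Y	433	29	1	CR5;CR55
miR-378	Y	169	17	0	CR66
miR-23b	Y	866	76	3	CR5;CR66
miR-122-5p	Y	187	23	0	CR67
miR-103a-3p	Y	433	29	1	CR5;CR68
miR-125b-5p	Y	476	21	0	CR5;CR66
miR-24	Y	552	38	0	CR66
let-7a	Y	435	24	0	CR66
miR-191-5p	N	55	1	0
miR-194-5p	N	291	20	1
miR-296-3p	N	364	17	1
miR-455-3p	N	305	13	0
miR-940	N	1024	75	1
let-7d-5p	Y	438	25	0	CR66
miR-22-3p	Y	430	17	0	CR66
miR-155-5p	N	311	19	0
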
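# 16 mature miRNAs differentially expressed in DCD liver primary non function
# (miRBase v21 mature identifiers and sequences; array fold change and p value).
# Columns: id, accession, sequence, fold_change, p_value
id	accession	sequence	fold_change	p_value
miR-107	MI0000114	agcagcauuguacagggcuauca	-1.8	0.02
miR-378	MIMAT0000731	cuccugacuccagguccugugu	-1.6	0.04
miR-23b	MIMAT0000418	uggguuccuggcaugcugauuu	-2.6	0.02
miR-122-5p	MIMAT0000421	uggagugugacaaugguguuug	-6	0.02
miR-103a-3p	MIMAT0000101	agcagcauuguacagggcuauga	-2.2	0.02
miR-125b-5p	MIMAT0000423	ucccugagacccuaacuuguga	-1.8	0.03
miR-24	MIMAT0000080	uggcucaguucagcaggaacag	-2	0.04
let-7a	MIMAT0000062	ugagguaguagguuguauaguu	-1.6	0.03
miR-191-5p	MIMAT0000440	caacggaaucccaaaagcagcug	-1.5	0.02
miR-194-5p	MIMAT0000460	uguaacagcaacuccaugugga	-1.6	0.04
miR-296-3p	MIMAT0004679	gaggguuggguggaggcucucc	-1.6	0.02
miR-455-3p	MIMAT0004784	gcaguccaugggcauauacac	-1.6	0.03
miR-940	MIMAT0004983	aaggcagggcccccgcucccc	-2	0.01
let-7d-5p	MIMAT0000065	agagguaguagguugcauaguu	-1.5	0.03
miR-22-3p	MIMAT0000077	aagcugccaguugaagaacugu	-1.6	0.047
miR-155-5p	MIMAT0000646	uuaaugcuaaucgugauaggggu	-2	0.01
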
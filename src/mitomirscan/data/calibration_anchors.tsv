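# Calibration anchors: published seed-site rows used to identify the seed-matching
# convention (window x complement geometry x strand labelling).
# Coordinates are in the numbering of the bundled NC_001807.4 reference. The published
# rows were numbered on the rCRS (NC_012920); NC_001807.4 carries two extra C's in the
# D-loop poly-C tract (~rCRS 303-315), lacks the rCRS 3107 placeholder N, and carries one
# extra C in the HVR1 poly-C tract (~rCRS 16184-16193), giving piecewise offsets
# +0 (1..~303), +2 (~316..3106), +1 (~3108..~16183), +2 (~16194..end) applied here.
# display_range preserves the published rCRS-numbered notation (trailing "r" = reverse /
# heavy strand, printed descending).
# The miR-24 41-46 row is anchored as published; it is expected to fail calibration (the
# published table's miR-24 block is internally garbled; see the calibration report).
# Columns: mirna_id, start, end, strand, display_range
mirna_id	start	end	strand	display_range
miR-378	5591	5596	forward	5590-5595
miR-378	5863	5868	reverse	5867-5862r
miR-122-5p	1235	1240	forward	1233-1238
miR-122-5p	15149	15154	reverse	15153-15148r
miR-23b	16056	16061	forward	16055-16060
miR-125b-5p	4812	4817	reverse	4816-4811r
let-7a	14378	14383	forward	14377-14382
let-7d-5p	15666	15671	forward	15665-15670
miR-24	41	46	forward	41-46
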
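mRNA	direction	miRNAs
CST4	Up	hsa-miR-1293
LTF	Down	hsa-miR-4306
CTSG	Up	hsa-miR-3664-5p
C3	Down	hsa-miR-4472/hsa-miR-4447/hsa-miR-508-5p/hsa-miR-1275
CSTA	Up	hsa-miR-138-5p
CPA3	Up	hsa-miR-196a-5p/hsa-miR-4502/hsa-miR-320c
KIT	Up	hsa-miR-19a-5p/hsa-miR-34a-5p/hsa-miR-4699-3p/hsa-miR-148b-3p/hsa-miR-30a-3p/hsa-miR-148a-3p/hsa-miR-193a-3p/hsa-miR-34c-5p/hsa-miR-3121-5p/hsa-miR-449b-5p/hsa-miR-30d-3p/hsa-miR-449a/hsa-miR-4789-3p/hsa-miR-548v/hsa-miR-221-3p
SERPINB2	Up	hsa-miR-33a-3p/hsa-miR-221-3p
GGH	Up	hsa-miR-30a-3p/hsa-miR-30d-3p
MUC5AC	Up	hsa-let-7b-5p
BPIFA1	Down	hsa-miR-4726-5p/hsa-miR-1275
SCGB1A1	Down	hsa-miR-654-5p
ADRA2A	Up	hsa-miR-23a-3p/hsa-miR-30a-5p/hsa-miR-3142/hsa-miR-23c/hsa-miR-339-5p
CD69	Up	hsa-miR-125b-5p/hsa-miR-92b-3p/hsa-miR-181a-5p/hsa-miR-125a-5p/hsa-miR-21-5p/hsa-miR-4699-5p
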
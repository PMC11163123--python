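# Published per-locus trio-consistency percentages, research-grade exome cohort (14 family trios).
# Rows verbatim as printed, including one locus label that appears twice in the original.
locus	first_field_pct	second_field_pct	third_field_pct	n
A	96.43	67.86	64.29	14
B	92.86	92.86	92.86	14
C	96.43	89.29	89.29	14
DRB1	89.29	82.14	82.14	14
DQA1	100	96.43	96.43	14
DQB1	96.43	78.57	78.57	14
DPA1	100	82.14	78.57	14
DPB1	57.14	57.14	57.14	14
DMA	100	100	100	14
DMB	100	82.14	82.14	14
DOA	100	100	92.86	14
DOB	100	100	100	14
DRA	100	100	96.43	14
DRB2	100	100	100	9
DRB3	100	91.67	87.5	12
DRB4	100	90	90	5
DRB5	100	100	100	2
DRB6	NA	NA	NA	0
DRB7	100	100	100	4
DRB9	100	100	100	4
DRB9	100	100	100	14
E	96.43	85.71	85.71	14
F	100	96.43	96.43	14
G	100	78.57	75	14
H	96.15	92.31	92.31	13
J	100	100	100	14
K	100	92.31	92.31	13
L	100	100	96.15	14
V	100	100	100	14
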
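# Published per-locus trio-consistency percentages, clinical-grade exome cohort (25 family trios).
locus	first_field_pct	second_field_pct	third_field_pct	n
A	100	100	98	25
B	96.15	94.87	94.87	25
C	98	98	98	25
DRB1	98	98	98	25
DQA1	100	100	100	25
DQB1	100	100	98	25
DPA1	98	98	98	25
DPB1	98	98	98	25
DMA	100	100	100	25
DMB	100	88	88	25
DOA	100	100	100	25
DOB	100	98	96	25
DRA	100	100	100	25
DRB2	100	100	100	11
DRB3	100	100	100	18
DRB4	100	100	100	13
DRB5	100	100	100	3
DRB6	NA	NA	NA	0
DRB7	100	100	100	5
DRB8	100	100	100	5
DRB9	100	96	96	25
E	100	100	96	25
F	100	100	100	25
G	100	100	96	25
H	86.96	86.96	84.78	23
J	100	100	100	25
K	100	88.1	88.1	21
L	100	100	100	25
V	100	100	100	23
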
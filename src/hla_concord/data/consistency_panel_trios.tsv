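# Published per-locus trio-consistency percentages, targeted HLA panel cohort (40 family trios, 11 loci).
locus	first_field_pct	second_field_pct	third_field_pct	n
A	100	98.75	98.75	40
B	100	100	100	40
C	100	100	100	40
DRB1	100	100	100	40
DQA1	100	100	100	40
DQB1	100	100	100	40
DPA1	100	100	100	40
DPB1	97.5	97.5	97.5	40
DRB3	94.45	90.28	88.89	24
DRB4	96.78	87.10	87.10	22
DRB5	100	100	100	20
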
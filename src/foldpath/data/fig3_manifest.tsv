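study	protein_id	intermediate_index	conformation_label	pdb_id	deposited_start	deposited_end	modeled_start	modeled_end	is_native	excluded	exclusion_reason
agirrezabala2022	nc1	1	a	70T5	1	27	2	27	false	false
agirrezabala2022	nc1	1	b	70T5	1	27	1	27	false	false
agirrezabala2022	nc1	1	c	70T5	1	27	1	27	false	false
agirrezabala2022	nc1	2	a	70II	1	70	40	70	false	true	major modeled-vs-deposited discrepancy
agirrezabala2022	nc1	2	b	70II	1	70	1	70	false	false
agirrezabala2022	nc1	2	c	1MJC	1	70	1	70	true	false
hanazono2018	nc2	1	a	5B3X	1	20	3	20	false	false
hanazono2018	nc2	2	a	5B3Y	1	45	25	45	false	true	major modeled-vs-deposited discrepancy
hanazono2018	nc2	3	a	6G4A	1	92	1	92	true	false
hanazono2016	nc3	1	a	5ZCA	1	24	4	24	false	false
hanazono2016	nc3	2	a	3W0A	1	48	2	48	false	false
hanazono2016	nc3	3	a	5ZCA	1	73	1	73	false	false
hanazono2016	nc3	4	a	3W0A	1	86	1	86	true	false
cabrita2016	nc4	1	a	2N62	1	114	1	114	true	false
cabrita2016	nc4	2	a	2N62	1	221	1	221	false	false
cabrita2016	nc4	2	b	2N62	1	221	1	221	false	false
cabrita2016	nc4	2	c	2N62	1	221	1	221	false	false
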
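sample_id	I	II	III	IV	V	VI	total_simple	n_compound	sequence_bp	density
SA1a	0	0	1	2	0	0	3	0	3556	0.8436
SA1b	0	1	0	2	0	0	3	0	3033	0.9891
SA2	0	2	1	0	0	0	3	0	3044	0.9855
SB1	0	2	0	1	0	0	3	1	3640	0.8242
SB2	0	2	0	1	0	0	3	1	3450	0.8696
Total	0	7	2	6	0	0	15	2	16723	0.897
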
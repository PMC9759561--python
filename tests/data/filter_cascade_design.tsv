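sample_id	group	replicate	pair_id	input_cells
Mock_1	Mock	1		12500000.0
Mock_2	Mock	2		12500000.0
Mock_3	Mock	3		12500000.0
Mock_4	Mock	4		12500000.0
GC7_1	GC7	1		32500000.0
GC7_2	GC7	2		32500000.0
GC7_3	GC7	3		32500000.0
GC7_4	GC7	4		32500000.0
WT_1	WT	1	P1	10000000.0
WT_2	WT	2	P2	10000000.0
WT_3	WT	3	P3	10000000.0
WT_4	WT	4	P4	10000000.0
KO_1	KO	1	P1	10000000.0
KO_2	KO	2	P2	10000000.0
KO_3	KO	3	P3	10000000.0
KO_4	KO	4	P4	10000000.0
Background_1	Background	1		12500000.0
Background_2	Background	2		12500000.0
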
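block_id	sub_label	subgenome_class	reference_lg	at_start	at_end
A	a	LF	A10	At1g02220	At1g07630
A	b	LF	A6	At1g07640	At1g19330
B		MF1	A8	At1g19850	At1g29020
N		MF1	A4	At3g51870	At3g62790
N		MF2	A7	At3g52770	At3g62790
Q	a	LF	A6	At5g23030	At5g28470
Q	b	LF	A3	At5g23030	At5g28470
S	a	MF1	A5	At5g33210	At5g37810
S	b	MF1	A7	At5g37830	At5g41900
U	a	MF1	A3	At4g16250	At4g24180
U	b	MF1	A6	At4g24190	At4g38770
X	a	LF	A3	At5g60810	At5g61760
X	b	LF	A6	At5g61770	At5g65925
X	c	LF	A7	At5g65930	At5g67385
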
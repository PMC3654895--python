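allele	supertype
A*0101	A1
A*0201	A2
A*0202	A2
A*0203	A2
A*0206	A2
A*0301	A3
A*1101	A3
A*2301	A24
A*2402	A24
A*2403	A24
A*2601	A1
A*2902	A3
A*3001	A3
A*3002	A1
A*3101	A3
A*3301	A3
A*6801	A3
A*6802	A2
A*6901	A2
B*0702	B7
B*1501	B62
B*1801	B62
B*3501	B7
B*4001	B44
B*4002	B44
B*4402	B44
B*4403	B44
B*4501	B44
B*5101	B7
B*5301	B7
B*5401	B7
B*5701	B58
B*5801	B58
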
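Aberrations	L 90x/N 30x	L 30x	Sum
Low hypodiploidy	-	1	1
High hyperdiploidy	11	3	14
t(12;21)	7	2	9
t(1;19)	3	2	5
iAMP(21)	5	1	6
t(9;22)	3	1	4
KMT2A-r	6	1	7
ABL-class	3	-	3
B-other	27/23	9	36
DS-ALL	3	-	3
Sum	68/64	20	88
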
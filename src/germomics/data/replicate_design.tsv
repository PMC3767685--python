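time	stained	radio	arrays
dormant	4	0	3
0.0	4	4	3
0.5	4	4	3
1.0	4	4	2
1.5	3	3	3
2.0	4	4	3
2.5	3	3	2
3.0	5	5	3
3.5	5	5	3
4.0	5	5	3
4.5	5	5	3
5.0	4	4	3
5.5	4	4	3
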
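chrom	length_bp
1	158532931
2	136231102
3	121005158
4	120000601
5	120089316
6	117806340
7	110682743
8	113319770
9	105454467
10	103308737
11	106982474
12	87216183
13	83472345
14	82403003
15	85007780
16	81013979
17	73167244
18	65820629
19	63449741
20	71974595
21	69862954
22	60773035
23	52498615
24	62317253
25	42350435
26	51992305
27	45612108
28	45940150
29	51098607
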
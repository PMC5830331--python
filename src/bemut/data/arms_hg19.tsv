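chrom	arm	start	end
1	p	0	121535434
1	q	124535434	249250621
2	p	0	92326171
2	q	95326171	243199373
3	p	0	90504854
3	q	93504854	198022430
4	p	0	49660117
4	q	52660117	191154276
5	p	0	46405641
5	q	49405641	180915260
6	p	0	58830166
6	q	61830166	171115067
7	p	0	58054331
7	q	61054331	159138663
8	p	0	43838887
8	q	46838887	146364022
9	p	0	47367679
9	q	50367679	141213431
10	p	0	39254935
10	q	42254935	135534747
11	p	0	51644205
11	q	54644205	135006516
12	p	0	34856694
12	q	37856694	133851895
13	p	0	16000000
13	q	19000000	115169878
14	p	0	16000000
14	q	19000000	107349540
15	p	0	17000000
15	q	20000000	102531392
16	p	0	35335801
16	q	38335801	90354753
17	p	0	22263006
17	q	25263006	81195210
18	p	0	15460898
18	q	18460898	78077248
19	p	0	24681782
19	q	27681782	59128983
20	p	0	26369569
20	q	29369569	63025520
21	p	0	11288129
21	q	14288129	48129895
22	p	0	13000000
22	q	16000000	51304566
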
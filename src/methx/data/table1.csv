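case_id,group,sex,age,survival_months,expression,methylation
1,tumor,F,71,1,Yes,Yes
2,tumor,M,70,13,Yes,Yes
3,tumor,F,73,8,Yes,Yes
4,tumor,M,64,14,No,Yes
5,tumor,M,64,4,Yes,No
6,tumor,F,72,11,Yes,No
7,tumor,F,74,4,Yes,Yes
8,tumor,F,84,0,No,Yes
9,tumor,F,86,1,Yes,Yes
10,tumor,F,70,18,Yes,No
11,tumor,M,84,2,Yes,No
12,tumor,M,49,15,Yes,Yes
13,tumor,M,76,1,No,Yes
14,tumor,F,63,7,Yes,Yes
N1,normal,F,62,,Yes,Yes
N2,normal,M,64,,Yes,Yes
N3,normal,F,40,,Yes,Yes
N4,normal,F,56,,Yes,Yes
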
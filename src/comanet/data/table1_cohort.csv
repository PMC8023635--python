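id,sex,age_years,ct_grade,days_since_injury,gcs_total,gose_3mo,gose_6mo
1,male,72,2,5,5,1,1
2,female,86,2,5,6,1,1
3,male,26,5,17,6,2,2
4,male,40,5,12,5,3,3
5,male,59,5,13,5,3,3
6,female,44,5,10,6,3,3
7,male,82,5,3,3,2,3
8,male,20,6,17,11,4,4
9,male,70,5,5,6,3,2
10,male,24,5,24,8,3,4
11,male,70,6,10,10,6,7
12,male,27,2,19,7,3,3
13,male,77,2,12,6,3,3
14,male,54,2,10,6,6,6
15,male,59,3,9,6,3,
16,female,59,5,14,8,3,3
17,male,61,2,15,8,4,6
18,male,32,2,17,10,4,5
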
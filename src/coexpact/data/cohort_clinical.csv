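patient_id,condition,activity,table_header,age_years,sex,duration_months,esr_mm_h,hscrp_mg_l,il6_pg_ml,tnfa_pg_ml,prednisone_mg_d
1,treated,inactive,Inactive (n=11),32,F,3,5,1,4.4,8.8,24
2,treated,inactive,Inactive (n=11),51,F,12,21,2.86,3,7.5,10
3,treated,inactive,Inactive (n=11),39,F,88,11,2.92,2,6.4,0
4,treated,inactive,Inactive (n=11),34,F,51,12,0.84,2,4,5
5,treated,inactive,Inactive (n=11),49,F,34,9,0.17,2,6,7.5
6,treated,inactive,Inactive (n=11),28,F,40,7,0.91,2,6.1,7.5
7,treated,inactive,Inactive (n=11),26,F,5,17,0.31,2,11,45
8,treated,inactive,Inactive (n=11),59,F,43,12,0.44,2,4,35
9,treated,inactive,Inactive (n=11),37,F,44,13,0.21,2.4,5.6,10
10,treated,active,Active (n=9),36,F,133,16,0.77,2,7.8,40
11,treated,active,Active (n=9),32,F,132,33,5.4,5.8,6.1,10
12,treated,active,Active (n=9),50,F,380,19,14.7,5.7,8,15
13,treated,active,Active (n=9),40,F,11,38,7.8,9.3,7.6,15
14,treated,active,Active (n=9),25,F,19,16,23.7,7.5,4,10
15,treated,active,Active (n=9),38,F,118,12,3.64,–,–,10
16,treated,active,Active (n=9),34,F,58,6,0.34,2,5.2,45
17,treated,active,Active (n=9),39,F,13,23,–,2.1,5.9,44
18,treated,active,Active (n=9),49,F,7,5,0.55,2.8,9.5,10
19,treated,active,Active (n=9),40,F,314,1,5.85,3.5,24.5,10
20,treated,active,Active (n=9),50,M,200,16,8.51,2,5.6,0
21,untreated,inactive,Inactive (n=3),34,F,176,7,0.34,2,4.3,0
22,untreated,inactive,Inactive (n=3),27,F,5,14,0.16,25.7,4,0
23,untreated,inactive,Inactive (n=3),38,F,48,5,0.32,3,4,0
24,untreated,active,Active (n=4),31,M,1,91,140.72,–,–,0
25,untreated,active,Active (n=4),25,F,1,19,11.28,6.3,5.2,0
26,untreated,active,Active (n=4),23,M,81,71,77.36,6.3,6.2,0
27,untreated,active,Active (n=4),29,F,4,127,113.62,22.2,8.4,0
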
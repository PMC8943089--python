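patient_id,y1_mm,y2_mm,x1_mm,l_mm
1,8.0,6.8,50,10
2,13.0,10.0,60,20
3,9.0,6.5,55,20
4,9.0,6.5,50,20
5,11.0,9.0,60,10
6,9.0,6.5,50,20
7,8.0,6.0,55,20
8,10.0,7.5,60,20
9,9.0,7.5,60,15
10,10.0,7.5,55,20
11,10.0,8.0,55,20
12,11.0,7.0,65,20
13,12.0,9.0,55,20
14,11.0,7.0,60,20
15,11.0,8.5,60,20
16,11.0,8.5,60,20
17,10.0,7.5,60,20
18,11.0,8.5,55,20
19,9.0,7.5,55,20
20,13.0,9.0,70,25
21,10.0,7.2,60,20
22,12.0,9.0,70,25
23,9.0,6.0,65,20
24,6.0,4.5,60,20
25,10.5,8.0,65,20
26,8.0,6.0,60,20
27,5.0,4.0,65,20
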
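case_id,group,general_right,general_left,neuro_right,neuro_left,ai_right,ai_left
1,normal,5.1,7.9,4.7,6.3,4.5,7.0
2,normal,5.6,8.5,6.5,8.7,6.5,7.0
3,normal,6.7,5.4,6.3,4.9,6.5,6.5
4,normal,7.0,9.1,8.0,8.9,6.5,10.0
5,normal,7.0,8.7,7.5,8.2,7.5,9.0
6,normal,7.4,5.3,6.9,5.9,6.5,6.5
7,normal,8.1,5.9,9.4,6.2,9.0,6.0
8,normal,8.6,8.4,8.9,8.6,9.5,7.0
9,normal,8.6,8.8,8.9,9.6,9.0,9.0
10,normal,9.0,8.5,8.9,8.7,7.5,8.0
11,abnormal,7.2,12.7,7.3,13.1,6.5,9.5
12,abnormal,10.2,5.3,11.1,5.8,11.5,5.0
13,abnormal,10.3,9.8,11.1,10.4,11.0,9.0
14,abnormal,10.3,5.6,9.3,5.1,9.0,5.0
15,abnormal,10.6,12.0,10.1,12.4,10.5,11.0
16,abnormal,11.3,10.5,11.2,10.5,10.5,9.5
17,abnormal,12.0,13.8,12.4,13.5,12.0,13.5
18,abnormal,12.1,12.1,12.5,12.5,15.0,14.5
19,abnormal,12.3,14.1,12.5,15.1,13.0,13.0
20,abnormal,14.1,12.8,14.5,12.3,14.0,12.0
21,abnormal,16.9,15.3,17.5,15.9,17.5,17.5
22,abnormal,22.0,26.6,22.9,26.3,22.5,27.5
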
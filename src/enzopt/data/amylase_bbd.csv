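run,cs_coded,cs_actual,ga_coded,ga_actual,time_coded,time_actual,specific_activity
1,1,3.0,1,1.5,0,16,86
2,1,3.0,0,1.0,1,24,308
3,0,2.5,0,1.0,0,16,217
4,0,2.5,-1,0.5,1,24,480
5,-1,2.0,0,1.0,1,24,540
6,-1,2.0,0,1.0,-1,6,477
7,1,3.0,-1,0.5,0,16,214
8,0,2.5,1,1.5,1,24,473
9,0,2.5,-1,0.5,-1,6,690
10,0,2.5,0,1.0,0,16,222
11,-1,2.0,-1,0.5,0,16,366
12,0,2.5,1,1.5,-1,6,462
13,-1,2.0,1,1.5,0,16,329
14,0,2.5,0,1.0,0,16,284
15,1,3.0,0,1.0,-1,6,483
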
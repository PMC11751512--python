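table,group_a,day_a,group_b,day_b,printed_p
1,C,0,CR,0,<0.05
1,C,1,CR,1,<0.05
1,T,0,TR,0,0.0627
1,T,1,TR,1,<0.0005
1,T,2,TR,2,<0.0005
1,S,0,SR,0,0.1174
1,S,1,SR,1,0.0508
1,S,2,SR,2,<0.0001
1,C,0,C,2,0.039
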
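table,group,kind,size_um,day,region,pct_radial,pct_peripheral,pct_oblique_near,pct_oblique_far,n,p_radial,p_peripheral,p_oblique_near,p_oblique_far
1,C,circle,300,0,piston,27.27,15.91,34.09,22.73,44,0.0011,0.2005,0.082,0.0034
1,CR,circle,300,0,control,0,27.78,16.67,55.56,36,,,,
1,C,circle,300,1,piston,40.79,9.21,26.32,23.68,76,0.2503,<0.0001,0.0433,0.2538
1,CR,circle,300,1,control,30.77,42.31,11.54,15.38,52,,,,
1,C,circle,300,2,piston,50.94,6.6,27.36,15.09,106,0.0001,0.0006,0.163,0.0009
1,CR,circle,300,2,control,17.54,26.32,17.54,38.65,70,,,,
1,T,triangle,300,0,piston,42.5,12.5,32.5,12.5,40,0.0462,0.114,0.4287,0.114
1,TR,triangle,300,0,control,23.88,25.37,25.37,25.37,67,,,,
1,T,triangle,300,1,piston,48.21,0,35.71,16.07,56,0.0161,0.0005,0.0778,0.0489
1,TR,triangle,300,1,control,27.14,20,21.43,31.43,70,,,,
1,T,triangle,300,2,piston,48.44,4.69,25,21.88,64,0.0001,0.0403,0.9677,0.0097
1,TR,triangle,300,2,control,17.65,15.29,24.71,42.35,85,,,,
1,S,square,300,0,piston,42.42,6.06,30.3,21.21,33,0.1075,0.0392,0.6581,0.5139
1,SR,square,300,0,control,26.67,22.67,34.67,16,75,,,,
1,S,square,300,1,piston,42.11,8.77,24.56,24.56,57,0.0167,0.0446,0.7957,0.5696
1,SR,square,300,1,control,22.89,21.69,26.51,28.92,83,,,,
1,S,square,300,2,piston,60.61,1.52,25.76,12.12,66,<0.0001,0.0043,0.3544,0.0034
1,SR,square,300,2,control,19.57,15.22,32.61,32.61,92,,,,
2,200,circle,200,0,piston,19.23,7.69,26.92,46.15,26,0.3204,0.1779,0.3894,0.2544
2,200R,circle,200,0,control,31.03,20.69,17.24,31.03,29,,,,
2,200,circle,200,1,piston,66.67,5.13,23.08,5.13,39,<0.0001,0.0057,0.4909,0.0113
2,200R,circle,200,1,control,12.12,30.3,30.3,27.27,33,,,,
2,200,circle,200,2,piston,73.81,2.38,11.9,11.9,42,0.0001,0.0027,0.2713,0.1029
2,200R,circle,200,2,control,26.32,26.32,21.05,26.32,38,,,,
2,250,circle,250,0,piston,43.33,13.33,13.33,30,30,0.097,0.5937,0.3821,0.5757
2,250R,circle,250,0,control,22.22,18.52,22.22,37.04,27,,,,
2,250,circle,250,1,piston,54.55,6.06,30.3,9.09,33,0.0091,0.0548,0.6747,0.0452
2,250R,circle,250,1,control,22.86,22.86,25.71,28.57,35,,,,
2,250,circle,250,2,piston,69.44,2.78,22.22,5.56,36,0.0004,0.0085,0.823,0.0259
2,250R,circle,250,2,control,26.83,24.39,24.39,24.39,41,,,,
2,280,circle,280,0,piston,40,6.67,20,33.33,15,0.5177,0.073,0.7774,0.4108
2,280R,circle,280,0,control,30.56,30.56,16.67,22.22,36,,,,
2,280,circle,280,1,piston,42.86,4.76,14.29,38.1,21,0.0237,0.0732,0.5587,0.8217
2,280R,circle,280,1,control,14.71,23.53,20.59,41.18,34,,,,
2,280,circle,280,2,piston,52.08,2.08,18.75,27.08,48,0.0017,0.0073,0.5966,0.3135
2,280R,circle,280,2,control,21.15,19.23,23.08,36.54,52,,,,
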
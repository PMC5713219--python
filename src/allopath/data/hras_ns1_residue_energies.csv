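group,residue,wt_mean,wt_sd,mut_mean,mut_sd
NS1,D29,-3.25,2.59,-1.56,2.39
NS1,Y30,-3.02,0.48,-2.05,0.77
NS1,K44,1.24,0.65,1.62,1.39
NS1,W72,-6.02,0.68,-5.32,0.73
NS1,W74,-2.11,0.91,-1.52,0.88
NS1,Y79,-8.96,0.87,-8.04,1.07
HRas,R128,-3.40,2.33,-1.15,2.38
HRas,Q131,-2.68,1.36,-2.01,1.21
HRas,R135K,-10.56,1.94,-2.75,3.27
HRas,I142,-2.65,0.76,-2.34,0.76
HRas,E143,-1.70,1.09,-0.94,1.29
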
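pair,wt_length,mut_length,wt_residues,mut_residues,wt_subopt,mut_subopt
R135(K)-R128,38,60,3,8,12,1
R135(K)-Q131,21,29,2,5,1,1
R135(K)-I142,68,61,4,8,9,0
R135(K)-E143,86,84,4,9,12,1
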
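term,wt_mean,wt_sd,mut_mean,mut_sd
dE_vdW,-68.36,4.36,-61.57,5.49
dE_ele,-75.44,31.88,-37.60,39.73
dG_GB,97.24,28.18,68.16,35.80
dG_SURF,-8.63,0.57,-7.46,0.78
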
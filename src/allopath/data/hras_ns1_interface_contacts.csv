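system,label,kind,resname_a,resseq_a,atom_a,resname_b,resseq_b,atom_b,distance
wt,Hb1,hbond,ASP,30,OD2,ARG,135,NH2,3.75
wt,Hb2,hbond,GLU,49,OE1,ARG,135,NE,2.73
wt,Hb3,hbond,GLU,49,OE2,ARG,135,NH1,2.89
wt,Hb4,hbond,TYR,82,OH,ARG,135,NH2,2.91
wt,Sb1,salt_bridge,ASP,30,OD2,ARG,135,NH2,3.75
wt,Sb2,salt_bridge,GLU,49,OE1,ARG,135,NE,2.73
wt,Sb3,salt_bridge,GLU,49,OE1,ARG,135,NH1,3.49
wt,Sb4,salt_bridge,GLU,49,OE2,ARG,135,NE,3.67
wt,Sb5,salt_bridge,GLU,49,OE2,ARG,135,NH1,2.89
mut,Sb1,salt_bridge,GLU,49,OE1,LYS,135,NZ,3.76
mut,Sb2,salt_bridge,GLU,49,OE2,LYS,135,NZ,3.96
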
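name,amount_umol_per_gDW,amount_per_cell_amol,c1_per_molecule
ATP,165.0,46.2,1
GTP,203.0,56.84,1
dATP,24.7,6.916,1
dGTP,25.4,7.112,1
dTTP,24.7,6.916,1
histidine,90.0,25.2,1
methionine,146.0,40.88,1
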
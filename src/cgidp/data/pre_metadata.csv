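protein,n_residues,n_labels,spectrometer_MHz,temperature_K,ionic_strength_M,pH
FUS,163,3,850,298,0.15,5.5
FUS12E,164,3,850,298,0.15,5.5
OPN,220,10,800,298,0.15,6.5
aSyn,140,5,700,283,0.2,7.4
A2,155,2,850,298,0.005,5.5
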
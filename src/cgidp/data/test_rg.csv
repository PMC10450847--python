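protein,n_residues,rg_nm,sigma_exp_nm,temperature_K,ionic_strength_M,pH
DSS1,71,2.5,0.1,288,0.17,7.4
p27Cv14,107,2.936,0.13,293,0.095,7.2
p27Cv15,107,2.915,0.10,293,0.095,7.2
p27Cv31,107,2.81,0.18,293,0.095,7.2
p27Cv44,107,2.492,0.13,293,0.095,7.2
p27Cv56,107,2.328,0.10,293,0.095,7.2
p27Cv78,107,2.211,0.03,293,0.095,7.2
PTMA,111,3.7,0.2,288,0.16,7.4
NHE6cmdd,116,3.2,0.2,288,0.17,7.4
A1_LCDstar_50mM,131,2.645,0.02,293,0.05,7.5
A1_LCDstar_150mM,131,2.65,0.02,293,0.15,7.5
A1_LCDstar_300mM,131,2.62,0.02,293,0.3,7.5
A1_LCDstar_500mM,131,2.528,0.02,293,0.5,7.5
ANAC046,167,3.6,0.3,298,0.14,7.0
Tau_2N3R,410,6.3,0.3,298,0.15,7.4
Tau_2N4R,441,6.7,0.3,298,0.15,7.4
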
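one_letter,lambda,sigma_nm,charge,mass_Da,pKa
A,0.0011162643859539,0.504,0,71.07,
C,0.5571899165031808,0.548,0,103.14,
D,0.0291821237763497,0.558,-1,115.09,
E,0.0061002816086497,0.592,-1,129.11,
F,0.9216959832175944,0.636,0,147.18,
G,0.7012713677972457,0.450,0,57.05,
H,0.4651948082346978,0.608,0,137.14,6.0
I,0.6075268330845265,0.618,0,113.16,
K,0.0586171731586979,0.636,1,128.17,
L,0.5563020305733198,0.594,0,113.16,
M,0.7458993420826714,0.618,0,131.20,
N,0.4383272997027284,0.568,0,114.10,
P,0.3729641853599348,0.556,0,97.12,
Q,0.3268188050525212,0.602,0,128.13,
R,0.7249915947715212,0.656,1,156.19,
S,0.4648570130065605,0.518,0,87.08,
T,0.2672387936544146,0.562,0,101.10,
V,0.4185006852559869,0.586,0,99.13,
W,0.9844235478393932,0.678,0,186.21,
Y,0.9950108229594324,0.646,0,163.18,
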
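one_letter,lambda,sigma_nm,charge,mass_Da,pKa
A,0.2743297969040348,0.504,0,71.07,
C,0.5615435099141777,0.548,0,103.14,
D,0.0416040480605567,0.558,-1,115.09,
E,0.0006935460962935,0.592,-1,129.11,
F,0.8672358982062975,0.636,0,147.18,
G,0.7058843733666401,0.450,0,57.05,
H,0.4663667290557992,0.608,0,137.14,6.0
I,0.5423623610671892,0.618,0,113.16,
K,0.1790211738990582,0.636,1,128.17,
L,0.6440005007782226,0.594,0,113.16,
M,0.5308481134337497,0.618,0,131.20,
N,0.4255859009787713,0.568,0,114.10,
P,0.3593126576364644,0.556,0,97.12,
Q,0.3934318551056041,0.602,0,128.13,
R,0.7307624767517166,0.656,1,156.19,
S,0.4625416811611541,0.518,0,87.08,
T,0.3713162976273964,0.562,0,101.10,
V,0.2083769608174481,0.586,0,99.13,
W,0.9893764740371644,0.678,0,186.21,
Y,0.9774611449343455,0.646,0,163.18,
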
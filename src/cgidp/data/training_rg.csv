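protein,n_residues,rg_nm,sigma_exp_nm,temperature_K,ionic_strength_M,pH
Hst5,24,1.38,0.05,293,0.15,7.5
Hst5x2,48,1.87,0.05,298,0.15,7.0
p53_20-70,62,2.39,0.05,277,0.1,7.0
ACTR,71,2.6,0.1,278,0.2,7.4
Ash1,81,2.9,0.05,293,0.15,7.5
CTD2,83,2.61,0.05,293,0.12,7.5
Sic1,92,3.0,0.4,293,0.2,7.5
SH4UD,95,2.7,0.1,293,0.2,8.0
ColNT,98,2.8,0.1,277,0.4,7.6
p15PAF,111,2.8,0.1,298,0.15,7.0
hNL3cyt,119,3.2,0.2,293,0.3,8.5
RNaseA,124,3.4,0.1,298,0.15,7.5
A1,137,2.76,0.02,298,0.15,7.0
-10R,137,2.67,0.01,298,0.15,7.0
-6R,137,2.57,0.01,298,0.15,7.0
+2R,137,2.62,0.02,298,0.15,7.0
+7R,137,2.71,0.01,298,0.15,7.0
-3R+3K,137,2.63,0.02,298,0.15,7.0
-6R+6K,137,2.79,0.01,298,0.15,7.0
-10R+10K,137,2.85,0.01,298,0.15,7.0
+12D,137,2.80,0.01,298,0.15,7.0
+4D,137,2.72,0.03,298,0.15,7.0
+8D,137,2.69,0.01,298,0.15,7.0
-9F+3Y,137,2.68,0.01,298,0.15,7.0
+12E,137,2.85,0.01,298,0.15,7.0
+7K+12D,137,2.92,0.01,298,0.15,7.0
+7K+12D_blocky,137,2.56,0.01,298,0.15,7.0
-4D,137,2.64,0.01,298,0.15,7.0
-8F+4Y,137,2.71,0.01,298,0.15,7.0
-10F+7R+12D,137,2.86,0.01,298,0.15,7.0
+7F-7Y,137,2.72,0.01,298,0.15,7.0
-12F+12Y,137,2.60,0.02,298,0.15,7.0
-12F+12Y-10R,137,2.61,0.02,298,0.15,7.0
-9F+6Y,137,2.65,0.01,298,0.15,7.0
aSyn,140,3.55,0.1,293,0.2,7.4
FhuA,144,3.34,0.1,298,0.15,7.5
K27,167,3.70,0.2,288,0.15,7.4
K10,168,4.00,0.1,288,0.15,7.4
K25,185,4.10,0.2,288,0.15,7.4
K32,198,4.20,0.3,288,0.15,7.4
CAHSD,227,4.8,0.2,293,0.07,7.0
K23,254,4.9,0.2,288,0.15,7.4
Tau35,255,4.7,0.1,298,0.15,7.4
CoRNID,271,4.7,0.2,293,0.2,7.5
K44,283,5.2,0.2,288,0.15,7.4
PNt,334,5.1,0.1,298,0.15,7.5
PNt_Swap1,334,4.9,0.1,298,0.15,7.5
PNt_Swap4,334,5.3,0.1,298,0.15,7.5
PNt_Swap5,334,4.9,0.1,298,0.15,7.5
PNt_Swap6,334,5.3,0.1,298,0.15,7.5
GHRICD,351,6.0,0.5,298,0.35,7.3
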
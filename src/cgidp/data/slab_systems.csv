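protein,n_residues,ionic_strength_mM,pH,temperature_K_rc4,temperature_K_rc2
Lge1_1-80_WT,114,100,7.5,,293
Lge1_1-80_-11R+11K,114,100,7.5,,293
Lge1_1-80_-14Y+14A,114,100,7.5,,293
A1_LCD_WT,137,150,7.0,310;323,277;293
A1_LCD_+7F-7Y,137,150,7.0,310;323,277;293
A1_LCD_-12F+12Y,137,150,7.0,310;323,277;293
A1_LCD_-23S+23T,137,150,7.0,310;323,277;293
A1_LCD_-14N+14Q,137,150,7.0,310;323,277;293
A1_LCD_-10G+10S,137,150,7.0,310;323,277;293
A1_LCD_-20G+20S,137,150,7.0,310;323,277;293
A1_LCD_-30G+30S,137,150,7.0,323,293
A1_LCD_+23G-23S,137,150,7.0,323,293
A1_LCD_+23G-23S+7F-7Y,137,150,7.0,323,293
A1_LCD_+23G-23S-12F+12Y,137,150,7.0,323,293
A1_LCD_-9F+3Y,137,150,7.0,310,277
A1_LCD_-8F+4Y,137,150,7.0,310,277
A1_LCD_-3R+3K,137,150,7.0,310,277
A1_LCD_-6R,137,150,7.0,310,277
A1_LCD_-4D,137,150,7.0,310,277
A1_LCD_+4D,137,150,7.0,310,277
A1_LCD_+8D,137,150,7.0,310,277
A1_LCD_+2R,137,150,7.0,310,277
A1_LCDstar_WT_150mM,131,150,7.0,323,293
A1_LCDstar_WT_200mM,131,200,7.0,323,293
A1_LCDstar_WT_300mM,131,300,7.0,323,293
A1_LCDstar_WT_500mM,131,500,7.0,323,293
LAF-1_RGG,176,150,7.5,323,293
LAF-1_RGG_shuffled,176,150,7.5,323,293
LAF-1_RGG_d21-30,166,150,7.5,323,293
A2_LCD,155,10,5.5,,297
FUS_LCD,163,150,7.4,,297
Ddx4_LCD,236,130,6.5,,297
Tau_2N4R,441,70,7.4,,
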
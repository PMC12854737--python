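# CI chondrite REE reference concentrations (ug/g), McDonough & Sun (1995)
element,concentration_ug_g
La,0.237
Ce,0.613
Pr,0.0928
Nd,0.457
Sm,0.148
Eu,0.0563
Gd,0.199
Tb,0.0361
Dy,0.246
Ho,0.0546
Er,0.160
Tm,0.0247
Yb,0.161
Lu,0.0246
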
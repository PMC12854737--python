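# Upper continental crust REE reference concentrations (ug/g), Rudnick & Gao (2003)
element,concentration_ug_g
La,31.0
Ce,63.0
Pr,7.1
Nd,27.0
Sm,4.7
Eu,1.0
Gd,4.0
Tb,0.7
Dy,3.9
Ho,0.83
Er,2.3
Tm,0.30
Yb,1.96
Lu,0.31
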
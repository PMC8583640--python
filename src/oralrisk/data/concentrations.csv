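metal,medium,unit,median,p25,p75
Mn,soil,mg/kg,344.19,299.02,450.69
Pb,soil,mg/kg,72.58,56.77,81.48
Cr,soil,mg/kg,73.65,46.21,96.04
Cd,soil,mg/kg,0.25,0.19,0.40
As,soil,mg/kg,7.82,4.83,12.31
Mn,food,mg/kg,0.47,0.35,0.65
Pb,food,mg/kg,0.10,0.04,0.25
Cr,food,mg/kg,0.13,0.08,0.18
Cd,food,mg/kg,0.007,0.001,0.013
As,food,mg/kg,0.018,0.014,0.030
Mn,water,ng/mL,0.59,0.33,1.03
Pb,water,ng/mL,0.13,0.07,0.22
Cr,water,ng/mL,0.94,0.44,2.21
Cd,water,ng/mL,0.01,0.01,0.01
As,water,ng/mL,1.41,0.89,1.78
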
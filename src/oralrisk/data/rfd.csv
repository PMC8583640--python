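metal,pathway,rfd_mg_per_kg_day
Mn,food,0.14
Mn,water,0.14
Mn,soil,0.14
Pb,food,0.0014
Pb,water,0.0014
Pb,soil,0.0014
Cr,food,1.5
Cr,water,3
Cr,soil,1.5
Cd,food,0.001
Cd,water,0.0005
Cd,soil,0.001
As,food,0.0003
As,water,0.0003
As,soil,0.0003
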
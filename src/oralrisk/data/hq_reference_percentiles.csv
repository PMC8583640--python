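metal,percentile,food,water,soil,sum
Mn,5,3.1e-2,2.1e-4,3.0e-4,3.1e-2
Mn,50,8.1e-2,3.4e-4,4.9e-3,8.6e-2
Mn,95,1.7e-1,4.6e-4,1.5e-2,1.8e-1
Pb,5,9.5e-3,5.0e-3,2.0e-2,3.4e-2
Pb,50,1.2,8.2e-3,9.9e-2,1.3
Pb,95,2.9,1.1e-2,2.6e-1,3.2
Cr,5,7.2e-4,1.6e-5,8.8e-6,7.5e-4
Cr,50,2.1e-3,2.7e-5,7.8e-5,2.2e-3
Cr,95,5.9e-3,3.6e-5,2.6e-4,6.2e-3
Cd,5,5.4e-5,6.1e-3,6.0e-5,6.3e-3
Cd,50,5.1e-2,1.0e-2,4.7e-4,6.2e-2
Cd,95,2.2e-1,1.4e-2,2.4e-3,2.4e-1
As,5,0,1.8e-1,3.0e-3,1.8e-1
As,50,5.8e-2,2.9e-1,3.0e-2,3.8e-1
As,95,5.3e-1,4.0e-1,1.5e-1,1.1
Total,5,7.0e-2,1.9e-1,2.3e-2,2.8e-1
Total,50,1.5,3.1e-1,1.3e-1,1.9
Total,95,3.9,4.2e-1,4.3e-1,4.8
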
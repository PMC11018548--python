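dinucleotide,shift,slide,rise,tilt,roll,twist
AA,-0.08,-1.27,3.18,-0.8,7.0,31.0
AC,0.23,-1.43,3.24,0.8,4.8,32.0
AG,-0.04,-1.50,3.30,0.5,8.5,30.0
AU,-0.06,-1.36,3.24,1.1,7.1,33.0
CA,0.11,-1.46,3.09,1.0,9.9,31.0
CC,-0.01,-1.78,3.32,0.3,8.7,32.0
CG,0.30,-1.89,3.30,-0.1,12.1,27.0
CU,-0.04,-1.50,3.30,0.5,8.5,30.0
GA,0.07,-1.70,3.38,1.3,9.4,32.0
GC,0.07,-1.39,3.22,0.0,6.1,35.0
GG,-0.01,-1.78,3.32,0.3,8.7,32.0
GU,0.23,-1.43,3.24,0.8,4.8,32.0
UA,-0.02,-1.45,3.26,-0.2,10.7,32.0
UC,0.07,-1.70,3.38,1.3,9.4,32.0
UG,0.11,-1.46,3.09,1.0,9.9,31.0
UU,-0.08,-1.27,3.18,-0.8,7.0,31.0
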
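aa,hydropathy,residue_mass,charge
A,1.8,71.079,0.0
R,-4.5,156.188,1.0
N,-3.5,114.104,0.0
D,-3.5,115.089,-1.0
C,2.5,103.144,0.0
Q,-3.5,128.131,0.0
E,-3.5,129.116,-1.0
G,-0.4,57.052,0.0
H,-3.2,137.141,0.1
I,4.5,113.160,0.0
L,3.8,113.160,0.0
K,-3.9,128.174,1.0
M,1.9,131.198,0.0
F,2.8,147.177,0.0
P,-1.6,97.117,0.0
S,-0.8,87.078,0.0
T,-0.7,101.105,0.0
W,-0.9,186.213,0.0
Y,-1.3,163.176,0.0
V,4.2,99.133,0.0
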
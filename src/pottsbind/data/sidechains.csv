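aa,bead,atom_type,charge,bond_length
A,CB,CALI,0.00,1.53
C,CB,CALI,0.10,1.53
C,SG,SULF,-0.10,1.81
D,CB,CALI,0.10,1.53
D,CG,COO,-1.10,1.52
E,CB,CALI,0.00,1.53
E,CG,CALI,0.10,1.53
E,CD,COO,-1.10,1.52
F,CB,CALI,0.00,1.53
F,RC,ARO,0.00,2.10
H,CB,CALI,-0.10,1.53
H,RN,IMID,0.10,2.00
I,CB,CALI,0.00,1.53
I,CG1,CALI,0.00,1.53
I,CD1,CH3,0.00,1.53
K,CB,CALI,0.00,1.53
K,CG,CALI,0.00,1.53
K,NZ,NH3,1.00,2.00
L,CB,CALI,0.00,1.53
L,CG,CALI,0.00,1.53
L,CD,CH3,0.00,1.53
M,CB,CALI,0.00,1.53
M,CG,CALI,0.00,1.53
M,SD,SME,0.00,1.81
N,CB,CALI,0.20,1.53
N,ND,AMD,-0.20,1.52
Q,CB,CALI,0.00,1.53
Q,CG,CALI,0.20,1.53
Q,NE,AMD,-0.20,1.52
R,CB,CALI,0.00,1.53
R,CG,CALI,0.00,1.53
R,NH,GUA,1.00,2.20
S,CB,CALI,0.25,1.53
S,OG,OH,-0.25,1.42
T,CB,CALI,0.25,1.53
T,OG,OH,-0.25,1.42
V,CB,CALI,0.00,1.53
V,CG,CH3,0.00,1.53
W,CB,CALI,0.00,1.53
W,RC1,ARO,0.00,2.10
W,RC2,ARO,0.00,2.30
Y,CB,CALI,0.00,1.53
Y,RC,ARO,0.25,2.10
Y,OH,OH,-0.25,2.80
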
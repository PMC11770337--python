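atom_type,charge,eps,rmin_half,gb_radius,element
NBB,-0.40,0.1700,1.8240,1.55,N
CAB,0.40,0.1094,1.9080,1.70,C
CBB,0.55,0.1094,1.9080,1.70,C
OBB,-0.55,0.2100,1.6612,1.52,O
CPE,0.00,0.1094,1.9080,1.70,C
CGQ,0.00,0.0000,3.0000,3.00,Q
CALI,0.00,0.1094,1.9080,1.70,C
CH3,0.00,0.1780,2.0000,1.70,C
ARO,0.00,0.2900,2.6000,2.00,C
OH,-0.25,0.2104,1.7210,1.52,O
SULF,0.00,0.2500,2.0000,1.80,S
SME,0.00,0.2500,2.0000,1.80,S
NH3,1.00,0.1700,1.8240,1.55,N
GUA,1.00,0.2100,2.2000,1.80,N
COO,-1.00,0.2100,1.9000,1.60,O
AMD,-0.20,0.2100,1.9000,1.60,N
IMID,0.10,0.2500,2.2000,1.90,N
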
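aa,chi1,chi2
A,,
G,,
C,-60,
C,60,
C,180,
D,-60,
D,60,
D,180,
F,-60,
F,60,
F,180,
H,-60,
H,60,
H,180,
N,-60,
N,60,
N,180,
S,-60,
S,60,
S,180,
T,-60,
T,60,
T,180,
V,-60,
V,60,
V,180,
E,-60,180
E,60,180
E,180,180
E,180,60
E,180,-60
I,-60,180
I,60,180
I,180,180
I,180,60
I,180,-60
K,-60,180
K,60,180
K,180,180
K,180,60
K,180,-60
L,-60,180
L,60,180
L,180,180
L,180,60
L,180,-60
M,-60,180
M,60,180
M,180,180
M,180,60
M,180,-60
Q,-60,180
Q,60,180
Q,180,180
Q,180,60
Q,180,-60
R,-60,180
R,60,180
R,180,180
R,180,60
R,180,-60
W,-60,180
W,60,180
W,180,180
W,180,60
W,180,-60
Y,-60,180
Y,60,180
Y,180,180
Y,180,60
Y,180,-60
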
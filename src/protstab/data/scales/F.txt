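code: F
class: other
source: Bhaskaran R., Ponnuswamy P.K. (1988) Int. J. Pept. Protein Res. 32:241-255 (ProtScale: Average flexibility)
description: Average flexibility index derived from structures of globular proteins.
A: 0.36
C: 0.35
D: 0.51
E: 0.5
F: 0.31
G: 0.54
H: 0.32
I: 0.46
K: 0.47
L: 0.37
M: 0.3
N: 0.46
P: 0.51
Q: 0.49
R: 0.53
S: 0.51
T: 0.44
V: 0.39
W: 0.31
Y: 0.42
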
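code: R
class: other
source: Jones D.D. (1975) J. Theor. Biol. 50:167-183 (ProtScale: Refractivity)
description: Refractivity; related to protein density and folding characteristics.
A: 4.34
C: 35.77
D: 12.0
E: 17.26
F: 29.4
G: 0.0
H: 21.81
I: 19.06
K: 21.29
L: 18.78
M: 21.64
N: 13.28
P: 10.93
Q: 17.56
R: 26.66
S: 6.35
T: 11.01
V: 13.92
W: 42.53
Y: 31.53
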
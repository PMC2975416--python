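code: Bu
class: structural
source: Zimmerman J.M., Eliezer N., Simha R. (1968) J. Theor. Biol. 21:170-201 (ProtScale: Bulkiness)
description: Bulkiness: ratio of the side-chain volume to the length of the amino acid.
A: 11.5
C: 13.46
D: 11.68
E: 13.57
F: 19.8
G: 3.4
H: 13.69
I: 21.4
K: 15.71
L: 21.4
M: 16.25
N: 12.82
P: 17.43
Q: 14.45
R: 14.28
S: 9.47
T: 15.77
V: 21.57
W: 21.67
Y: 18.03
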
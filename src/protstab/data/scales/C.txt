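code: C
class: structural
source: Deleage G., Roux B. (1987) Protein Eng. 1:289-294 (ProtScale: coil / Deleage & Roux)
description: Conformational parameter for coil.
A: 0.824
C: 0.953
D: 1.197
E: 0.761
F: 0.797
G: 1.251
H: 1.068
I: 0.886
K: 0.897
L: 0.771
M: 0.81
N: 1.167
P: 1.54
Q: 0.947
R: 0.893
S: 1.13
T: 1.148
V: 0.772
W: 0.941
Y: 1.109
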
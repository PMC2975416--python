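code: A
class: structural
source: Deleage G., Roux B. (1987) Protein Eng. 1:289-294 (ProtScale: alpha helix / Deleage & Roux)
description: Conformational parameter for alpha-helix.
A: 1.489
C: 0.966
D: 0.924
E: 1.504
F: 1.195
G: 0.51
H: 1.003
I: 1.003
K: 1.172
L: 1.236
M: 1.363
N: 0.772
P: 0.492
Q: 1.164
R: 1.224
S: 0.739
T: 0.785
V: 0.99
W: 1.09
Y: 0.787
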
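code: B
class: structural
source: Deleage G., Roux B. (1987) Protein Eng. 1:289-294 (ProtScale: beta sheet / Deleage & Roux)
description: Conformational parameter for beta-sheet.
A: 0.709
C: 1.191
D: 0.541
E: 0.567
F: 1.393
G: 0.657
H: 0.863
I: 1.799
K: 0.721
L: 1.261
M: 1.21
N: 0.604
P: 0.354
Q: 0.84
R: 0.92
S: 0.928
T: 1.221
V: 1.965
W: 1.306
Y: 1.266
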
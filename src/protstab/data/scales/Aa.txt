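code: Aa
class: structural
source: Rose G.D. et al. (1985) Science 229:834-838 (ProtScale: Average area buried)
description: Average area buried on transfer from standard state to folded protein (A^2).
A: 86.6
C: 132.3
D: 97.8
E: 113.9
F: 194.1
G: 62.9
H: 155.8
I: 158.0
K: 115.5
L: 164.1
M: 172.9
N: 103.3
P: 92.9
Q: 119.2
R: 162.2
S: 85.6
T: 106.5
V: 141.0
W: 224.6
Y: 177.7
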
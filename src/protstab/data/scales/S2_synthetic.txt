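code: S2
class: empirical
source: SYNTHETIC STAND-IN constructed for this package (qualitative analogue of a mutation-experiment-derived relative stability scale)
description: Relative protein stability scale derived from mutation experiments. SYNTHETIC STAND-IN: constructed values reproducing the qualitative ordering only, not the published numbers.
A: 0.25
C: 0.9
D: -0.4
E: -0.35
F: 1.1
G: -0.85
H: 0.05
I: 1.25
K: -0.55
L: 1.15
M: 0.8
N: -0.45
P: -0.7
Q: -0.3
R: -0.5
S: -0.2
T: 0.1
V: 1.05
W: 0.95
Y: 0.6
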
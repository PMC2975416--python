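code: S3
class: empirical
source: SYNTHETIC STAND-IN constructed for this package (qualitative analogue of a denaturation-experiment side-chain stability contribution scale)
description: Side-chain contribution to protein stability (kcal/mol-like units). SYNTHETIC STAND-IN: constructed values reproducing the qualitative ordering only, not the published numbers.
A: 0.45
C: 1.3
D: -0.25
E: -0.1
F: 1.75
G: -0.95
H: 0.4
I: 1.85
K: -0.3
L: 1.65
M: 1.2
N: -0.2
P: -0.6
Q: -0.05
R: 0.0
S: -0.15
T: 0.25
V: 1.5
W: 1.6
Y: 1.05
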
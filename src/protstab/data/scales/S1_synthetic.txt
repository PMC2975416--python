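code: S1
class: empirical
source: SYNTHETIC STAND-IN constructed for this package (qualitative analogue of an atom-atom potential-of-mean-force stability scale)
description: Protein stability scale from a knowledge-based atom-atom potential. SYNTHETIC STAND-IN: the original table is not redistributed here; these values were constructed to reproduce the qualitative ordering (buried hydrophobics stabilizing, charged/Gly/Pro destabilizing), not the published numbers.
A: 0.3
C: 1.2
D: -0.65
E: -0.6
F: 1.55
G: -0.5
H: 0.1
I: 1.6
K: -0.8
L: 1.5
M: 1.1
N: -0.55
P: -0.35
Q: -0.45
R: -0.7
S: -0.25
T: 0.0
V: 1.4
W: 1.35
Y: 0.85
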
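code: Tt
class: other
source: Zhao G., London E. (2006) Protein Sci. 15:1987-2001 (ProtScale: Transmembrane tendency)
description: Transmembrane tendency of the amino acid.
A: 0.38
C: -0.3
D: -3.27
E: -2.9
F: 1.98
G: -0.19
H: -1.44
I: 1.97
K: -3.46
L: 1.82
M: 1.4
N: -1.62
P: -1.44
Q: -1.84
R: -2.57
S: -0.53
T: -0.32
V: 1.46
W: 1.53
Y: 0.49
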
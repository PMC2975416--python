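code: Rf
class: other
source: Fraga S. (1982) Can. J. Chem. 60:2606-2610 (ProtScale: Recognition factors)
description: Recognition factor: average stabilization energy of the amino acid in contacts.
A: 78
C: 89
D: 81
E: 78
F: 81
G: 84
H: 84
I: 88
K: 87
L: 85
M: 80
N: 94
P: 91
Q: 87
R: 95
S: 107
T: 93
V: 89
W: 104
Y: 84
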
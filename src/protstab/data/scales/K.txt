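code: K
class: biochemical
source: CRC Handbook of Chemistry and Physics side-chain ionization constants; 7.00 assigned to non-ionizable side chains (package convention)
description: Side-chain pKa; governs the ionization state of a residue and pH-dependent stability.
A: 7.0
C: 8.18
D: 3.65
E: 4.25
F: 7.0
G: 7.0
H: 6.0
I: 7.0
K: 10.53
L: 7.0
M: 7.0
N: 7.0
P: 7.0
Q: 7.0
R: 12.48
S: 7.0
T: 7.0
V: 7.0
W: 7.0
Y: 10.07
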
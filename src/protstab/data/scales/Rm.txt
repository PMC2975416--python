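code: Rm
class: other
source: Dayhoff M.O., Schwartz R.M., Orcutt B.C. (1978) Atlas of Protein Sequence and Structure 5(3):345-352 (ProtScale: Relative mutability, Ala=100)
description: Relative mutability: probability that the amino acid changes to another over evolution.
A: 100
C: 20
D: 106
E: 102
F: 41
G: 49
H: 66
I: 96
K: 56
L: 40
M: 94
N: 134
P: 56
Q: 93
R: 65
S: 120
T: 97
V: 74
W: 18
Y: 41
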
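code: Mc
class: other
source: Aboderin A.A. (1971) Int. J. Biochem. 2:537-544 (ProtScale: Mobility on chromatography paper)
description: Mobility of the amino acid on chromatography paper (RF).
A: 5.1
C: 0.0
D: 0.7
E: 1.8
F: 13.2
G: 4.1
H: 1.6
I: 16.8
K: 1.3
L: 10.0
M: 5.5
N: 0.6
P: 8.0
Q: 1.4
R: 2.0
S: 1.2
T: 2.7
V: 13.0
W: 14.9
Y: 6.1
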
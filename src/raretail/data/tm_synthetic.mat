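# Synthetic transmembrane-region substitution matrix (non-symmetric).
# Stand-in for helix-specific matrices such as SLIM; BLOSUM62 plus a
# hydrophobic-pair bonus and an asymmetric query-hydrophobicity term.
   A  C  D  E  F  G  H  I  K  L  M  N  P  Q  R  S  T  V  W  Y
A   5  -1  -3  -2  -1  -1  -3   0  -2   0   0  -3  -2  -2  -2   0  -1   1  -2  -1
C   0   9  -3  -4  -2  -3  -3  -1  -3  -1  -1  -3  -3  -3  -3  -1  -1  -1  -2  -2
D  -2  -3   6   2  -3  -1  -1  -3  -1  -4  -3   1  -1   0  -2   0  -1  -3  -4  -3
E  -1  -4   2   5  -3  -2   0  -3   1  -3  -2   0  -1   2   0   0  -1  -2  -3  -2
F  -1  -3  -4  -4   7  -4  -2   1  -4   1   1  -4  -5  -4  -4  -3  -3   0   2   4
G   0  -3  -1  -2  -3   6  -2  -4  -2  -4  -3   0  -2  -2  -2   0  -2  -3  -2  -3
H  -2  -3  -1   0  -1  -2   8  -3  -1  -3  -2   1  -2   0   0  -1  -2  -3  -2   2
I   0  -2  -4  -4   1  -5  -4   5  -4   3   2  -4  -4  -4  -4  -3  -2   4  -2   0
K  -1  -3  -1   1  -3  -2  -1  -3   5  -2  -1   0  -1   1   2   0  -1  -2  -3  -2
L   0  -2  -5  -4   1  -5  -4   3  -3   5   3  -4  -4  -3  -3  -3  -2   2  -1   0
M   0  -2  -4  -3   1  -4  -3   2  -2   3   6  -3  -3  -1  -2  -2  -2   2   0   0
N  -2  -3   1   0  -3   0   1  -3   0  -3  -2   6  -2   0   0   1   0  -3  -4  -2
P  -1  -3  -1  -1  -4  -2  -2  -3  -1  -3  -2  -2   7  -1  -2  -1  -1  -2  -4  -3
Q  -1  -3   0   2  -3  -2   0  -3   1  -2   0   0  -1   5   1   0  -1  -2  -2  -1
R  -1  -3  -2   0  -3  -2   0  -3   2  -2  -1   0  -2   1   5  -1  -1  -3  -3  -2
S   1  -1   0   0  -2   0  -1  -2   0  -2  -1   1  -1   0  -1   4   1  -2  -3  -2
T   0  -1  -1  -1  -2  -2  -2  -1  -1  -1  -1   0  -1  -1  -1   1   5   0  -2  -2
V   1  -2  -4  -3   0  -4  -4   4  -3   2   2  -4  -3  -3  -4  -3  -1   5  -2   0
W  -2  -3  -5  -4   2  -3  -3  -2  -4  -1   0  -5  -5  -3  -4  -4  -3  -2  12   3
Y  -1  -3  -4  -3   4  -4   1   0  -3   0   0  -3  -4  -2  -3  -3  -3   0   3   8
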
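# Default PB substitution matrix, v1.
# Geometry-derived similarity: s(x, y) = 6 - 0.15 * RMSDA(x, y) rounded to
# 0.1, where RMSDA is the root-mean-square wrapped angular difference (deg)
# between the 8-dihedral prototype vectors of PBs x and y (see
# pb_prototypes.tsv). Symmetric with a uniform dominant diagonal of 6.
# Users may substitute an empirically derived matrix via load_matrix().
  a  b  c  d  e  f  g  h  i  j  k  l  m  n  o  p
a    6.0   -7.8   -4.8   -6.4   -9.5   -8.4   -7.0  -10.6   -9.3   -9.9  -10.9   -8.7   -9.6  -11.0   -9.4   -7.9
b   -7.8    6.0   -4.5   -2.8   -6.8   -6.9   -8.0   -7.7   -3.5   -7.7   -3.9   -6.8   -9.4  -11.0   -9.3   -6.8
c   -4.8   -4.5    6.0   -2.4   -6.5   -5.3   -5.0   -8.1   -8.0   -7.5   -8.5  -10.4   -9.4  -10.7   -8.7   -5.8
d   -6.4   -2.8   -2.4    6.0   -3.7   -3.2   -8.2   -6.3   -5.7   -5.5   -7.2   -9.8  -13.3  -14.3  -12.2  -10.1
e   -9.5   -6.8   -6.5   -3.7    6.0   -6.1   -4.5   -8.3   -9.0   -8.2   -8.5  -10.9  -14.0  -11.2  -14.0  -12.0
f   -8.4   -6.9   -5.3   -3.2   -6.1    6.0   -9.9   -2.3   -8.9   -4.6   -3.3   -6.8   -9.8  -11.8  -10.5  -11.0
g   -7.0   -8.0   -5.0   -8.2   -4.5   -9.9    6.0  -11.1  -10.8  -12.0  -10.5   -9.3   -8.3   -4.1   -8.4   -7.3
h  -10.6   -7.7   -8.1   -6.3   -8.3   -2.3  -11.1    6.0   -9.7   -6.7   -5.3   -8.5  -11.1  -13.3   -7.9  -11.8
i   -9.3   -3.5   -8.0   -5.7   -9.0   -8.9  -10.8   -9.7    6.0   -5.2   -6.0   -8.4  -11.7  -12.9  -12.6   -4.7
j   -9.9   -7.7   -7.5   -5.5   -8.2   -4.6  -12.0   -6.7   -5.2    6.0   -4.4   -7.9   -9.9  -11.9  -13.0   -8.7
k  -10.9   -3.9   -8.5   -7.2   -8.5   -3.3  -10.5   -5.3   -6.0   -4.4    6.0   -3.5   -6.8   -9.1   -9.3   -9.3
l   -8.7   -6.8  -10.4   -9.8  -10.9   -6.8   -9.3   -8.5   -8.4   -7.9   -3.5    6.0   -3.6   -6.3   -6.8   -8.4
m   -9.6   -9.4   -9.4  -13.3  -14.0   -9.8   -8.3  -11.1  -11.7   -9.9   -6.8   -3.6    6.0   -2.2   -3.0   -6.1
n  -11.0  -11.0  -10.7  -14.3  -11.2  -11.8   -4.1  -13.3  -12.9  -11.9   -9.1   -6.3   -2.2    6.0   -7.0   -7.8
o   -9.4   -9.3   -8.7  -12.2  -14.0  -10.5   -8.4   -7.9  -12.6  -13.0   -9.3   -6.8   -3.0   -7.0    6.0   -7.4
p   -7.9   -6.8   -5.8  -10.1  -12.0  -11.0   -7.3  -11.8   -4.7   -8.7   -9.3   -8.4   -6.1   -7.8   -7.4    6.0
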
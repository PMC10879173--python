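# Refined theta-ribozyme search motif (final iteration).
# Tightened element lengths and identity constraints relative to the minimal
# delta-ribozyme motif, plus one additional degree of freedom at the last
# position of the J4/2 junction (degenerate constraint, element j42x).
order: p1 j12 p2 p3 l3a p11 l3b p3' j31 p1' p11' p4 l4 p4' j42 j42x p2'
p1   6:6  GNNNNN  wobble=1
j12  2:2  NC
p2   4:4  -       wobble=1
p3   3:3  -       wobble=1
l3a  3:3  CGN
p11  2:2  -       wobble=0
l3b  1:1  -
j31  0:3  -
p4   2:2  -       wobble=1
l4   2:2  -
j42  4:6  CNNNNN
j42x 1:1  H
catalytic: j42 0
cleavage: p1
nratio: 0.1
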
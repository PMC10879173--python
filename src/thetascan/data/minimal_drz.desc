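# Minimal HDV-like (delta) ribozyme search motif.
# Nested double pseudoknot: P1, P1.1, P2, P3 and a short P4/L4 hairpin;
# cleavage occurs 5' of the first nucleotide of P1 (G1); the catalytic
# cytosine is the first position of the J4/2 junction.
order: p1 j12 p2 p3 l3a p11 l3b p3' j31 p1' p11' p4 l4 p4' j42 p2'
p1   6:7  GNNNNNN  wobble=1
j12  1:3  -
p2   4:5  -        wobble=1
p3   3:3  -        wobble=1
l3a  2:4  -
p11  2:2  -        wobble=0
l3b  0:2  -
j31  0:4  -
p4   2:2  -        wobble=1
l4   2:4  -
j42  4:7  CNNNNNN
catalytic: j42 0
cleavage: p1
nratio: 0.1
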
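# Default peptide-binding-region (PBR) mask for DRB1 beta1-domain codons.
# 1-based mature-protein codon positions; use offset=29 on complete CDS
# (29-codon signal peptide) or offset=0 on mature-protein alignments.
#
# 24 peptide-contact residues of the DR beta1 groove plus positions 57, 67
# and 90, for 27 codons in total.  Editable: every analysis accepts any
# mask file in this format.
9
11
13
26
28
30
32
37
38
47
56
57
60
61
65
67
68
70
71
74
78
81
82
85
86
89
90
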
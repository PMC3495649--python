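haplotype,30,58,79,97,163,164,172,204,208,326,337,357,398,431,486,521,586,619
H1,C,C,C,C,T,G,T,G,A,G,A,C,C,A,C,A,C,G
H2,C,T,C,C,C,G,T,G,G,G,A,C,C,G,C,A,T,G
H3,C,C,C,C,C,G,T,G,A,G,A,C,C,A,C,A,C,G
H4,C,T,C,C,C,G,T,G,A,G,A,C,C,G,C,A,T,G
H5,C,T,C,C,C,G,T,G,A,G,A,C,C,G,C,A,T,A
H6,C,C,C,C,C,G,T,G,A,G,A,T,C,A,C,A,C,G
H7,C,T,C,C,C,A,T,G,A,G,A,C,C,G,C,A,T,G
H8,C,T,C,C,C,G,T,T,A,G,A,C,C,G,C,A,T,G
H9,C,C,C,C,C,G,C,G,A,G,G,C,C,G,C,A,T,G
H10,C,T,C,C,C,G,T,G,A,G,A,C,C,G,T,A,T,G
H11,T,C,C,C,C,G,T,G,A,G,A,C,T,A,C,A,C,G
H12,C,T,C,C,C,G,T,G,G,G,A,C,C,G,C,C,T,G
H13,C,C,T,C,C,G,C,G,A,G,A,C,C,G,C,A,T,G
H14,C,T,C,T,C,G,T,G,A,G,A,C,C,G,C,A,T,G
H15,T,C,C,C,C,G,T,G,A,G,A,C,C,A,C,A,C,G
H16,C,C,C,C,C,G,C,G,A,G,A,C,C,G,C,A,T,G
H17,C,T,C,C,C,G,T,G,A,A,A,C,C,G,C,A,T,G
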
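haplotype,11,84,90,101,102,146,163,216,251,256,364,407,586,617,623,773,789,819
C1,-,T,T,A,*,G,-,C,-,C,A,A,G,A,A,C,-,C
C2,T,T,G,A,*,G,-,C,-,C,A,A,G,C,A,C,-,C
C3,-,G,T,A,*,G,-,C,-,C,A,A,G,A,A,C,-,C
C4,-,T,T,A,*,G,-,C,-,C,C,A,G,A,A,C,-,C
C5,-,T,T,A,*,G,-,C,-,C,A,A,G,A,A,T,-,C
C6,-,T,T,A,*,G,-,C,-,T,A,A,G,A,A,C,-,C
C7,-,G,T,C,*,T,-,T,-,C,A,T,G,A,A,C,-,C
C8,-,T,T,A,-,G,-,C,-,C,A,A,G,A,A,C,-,C
C9,-,T,G,A,*,G,A,C,-,C,A,A,T,A,C,C,-,T
C10,-,G,T,C,*,G,-,C,T,C,A,A,G,A,A,C,-,C
C11,-,G,T,C,*,G,-,C,-,C,A,A,G,A,A,C,-,C
C12,-,T,G,A,*,G,-,C,-,C,A,A,G,A,A,C,#,C
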
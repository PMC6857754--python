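child,parent
C,ICD10
E,ICD10
F,ICD10
I,ICD10
M,ICD10
N,ICD10
C50,C
C50.9,C50
E11,E
E11.0,E11
E11.9,E11
E55,E
E55.9,E55
E66,E
E66.9,E66
F32,F
F32.0,F32
F32.9,F32
F33,F
F33.9,F33
I10,I
I20,I
I20.9,I20
I25,I
I25.1,I25
I25.9,I25
M54,M
M54.5,M54
M81,M
M81.9,M81
N04,N
N04.9,N04
N20,N
N20.0,N20
N20.1,N20
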
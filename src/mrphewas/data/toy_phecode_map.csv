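icd10,phecode,exclusion_min,exclusion_max,sex
C50.9,174.1,174,175.99,F
E11.0,250.2,249,250.99,
E11.9,250.2,249,250.99,
E55.9,261.4,260,261.99,
E66.9,278.1,278,278.99,
F32.0,296.2,296,296.99,
F32.9,296.2,296,296.99,
F33.9,296.2,296,296.99,
I10,401.1,401,405.99,
I20.9,411.2,410,414.99,
I25.1,411.4,410,414.99,
I25.9,411.4,410,414.99,
M54.5,760.0,760,760.99,
M81.9,743.1,743,743.99,
N04.9,580.3,580,580.99,
N20.0,594.1,594,594.99,
N20.1,594.1,594,594.99,
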
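snp_id,effect_allele,other_allele,effect_allele_freq,weight
rs3755967,T,C,0.292071,0.089
rs12785878,T,G,0.789727,0.036
rs10741657,A,G,0.404264,0.031
rs17216707,T,C,0.817665,0.026
rs10745742,T,C,0.376848,0.017
rs8018720,G,C,0.176514,0.013
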
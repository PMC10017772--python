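allele	assignment	provenance
3DL1*001	high	surface-density phenotyping class (h)
3DL1*002	high	surface-density phenotyping class (h)
3DL1*008	high	surface-density phenotyping class (h)
3DL1*015	high	surface-density phenotyping class (h)
3DL1*020	high	surface-density phenotyping class (h)
3DL1*005	low	surface-density phenotyping class (l)
3DL1*007	low	surface-density phenotyping class (l)
3DL1*004	null	intracellular retention class (n)
3DS1*013	3DS1	surface-expressed, does not bind Bw4
3DS1*049	3DS1	surface-expressed, does not bind Bw4
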
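allele	assignment	provenance
2DL1*001	R	transmembrane residue 245 arginine
2DL1*002	R	transmembrane residue 245 arginine
2DL1*003	R	transmembrane residue 245 arginine
2DL1*004	C	transmembrane residue 245 cysteine
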
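allele	assignment	provenance
A*23	Bw4	serology-derived Bw4 motif on HLA-A (allele group)
A*24	Bw4	serology-derived Bw4 motif on HLA-A (allele group)
A*25	Bw4	serology-derived Bw4 motif on HLA-A (allele group)
A*32	Bw4	serology-derived Bw4 motif on HLA-A (allele group)
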
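allele	assignment	provenance
B*07:02	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*07:05	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*08:01	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*13:01	Bw4-80T	Asp77/Thr80, IPD-IMGT/HLA reference protein
B*13:02	Bw4-80T	Asp77/Thr80, IPD-IMGT/HLA reference protein
B*14:01	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*14:02	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*15:01	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*15:03	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*18:01	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*27:05	Bw4-80T	Asp77/Thr80, IPD-IMGT/HLA reference protein
B*35:01	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*35:02	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*35:03	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*35:08	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*37:01	Bw4-80T	Asp77/Thr80, IPD-IMGT/HLA reference protein
B*38:01	Bw4-80I	Asp77/Ile80, IPD-IMGT/HLA reference protein
B*39:01	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*39:06	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*40:01	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*40:02	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*41:01	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*41:02	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*42:01	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*44:02	Bw4-80T	Asp77/Thr80, IPD-IMGT/HLA reference protein
B*44:03	Bw4-80T	Asp77/Thr80, IPD-IMGT/HLA reference protein
B*45:01	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*47:01	Bw4-80T	Asp77/Thr80, IPD-IMGT/HLA reference protein
B*48:01	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*49:01	Bw4-80T	Asp77/Thr80, IPD-IMGT/HLA reference protein
B*50:01	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*51:01	Bw4-80I	Asp77/Ile80, IPD-IMGT/HLA reference protein
B*52:01	Bw4-80I	Asp77/Ile80, IPD-IMGT/HLA reference protein
B*53:01	Bw4-80I	Asp77/Ile80, IPD-IMGT/HLA reference protein
B*54:01	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*55:01	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*56:01	Bw6	Asn77/Asn80, IPD-IMGT/HLA reference protein
B*57:01	Bw4-80I	Asp77/Ile80, IPD-IMGT/HLA reference protein
B*57:03	Bw4-80I	Asp77/Ile80, IPD-IMGT/HLA reference protein
B*58:01	Bw4-80I	Asp77/Ile80, IPD-IMGT/HLA reference protein
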
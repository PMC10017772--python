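allele	assignment	provenance
C*01:02	C1	Asn80, IPD-IMGT/HLA reference protein
C*02:02	C2	Lys80, IPD-IMGT/HLA reference protein
C*03:02	C1	Asn80, IPD-IMGT/HLA reference protein
C*03:03	C1	Asn80, IPD-IMGT/HLA reference protein
C*03:04	C1	Asn80, IPD-IMGT/HLA reference protein
C*04:01	C2	Lys80, IPD-IMGT/HLA reference protein
C*05:01	C2	Lys80, IPD-IMGT/HLA reference protein
C*06:02	C2	Lys80, IPD-IMGT/HLA reference protein
C*07:01	C1	Asn80, IPD-IMGT/HLA reference protein
C*07:02	C1	Asn80, IPD-IMGT/HLA reference protein
C*07:04	C1	Asn80, IPD-IMGT/HLA reference protein
C*08:01	C1	Asn80, IPD-IMGT/HLA reference protein
C*08:02	C1	Asn80, IPD-IMGT/HLA reference protein
C*12:02	C1	Asn80, IPD-IMGT/HLA reference protein
C*12:03	C1	Asn80, IPD-IMGT/HLA reference protein
C*14:02	C1	Asn80, IPD-IMGT/HLA reference protein
C*15:02	C2	Lys80, IPD-IMGT/HLA reference protein
C*16:01	C1	Asn80, IPD-IMGT/HLA reference protein
C*16:02	C2	Lys80, IPD-IMGT/HLA reference protein
C*17:01	C2	Lys80, IPD-IMGT/HLA reference protein
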
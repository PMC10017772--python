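allele	assignment	provenance
B*07:02	M	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*07:05	M	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*08:01	M	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*13:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*13:02	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*14:01	M	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*14:02	M	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*15:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*15:03	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*18:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*27:05	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*35:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*35:02	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*35:03	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*35:08	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*37:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*38:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*39:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*39:06	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*40:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*40:02	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*41:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*41:02	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*42:01	M	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*44:02	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*44:03	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*45:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*47:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*48:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*49:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*50:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*51:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*52:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*53:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*54:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*55:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*56:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*57:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*57:03	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
B*58:01	T	leader peptide residue -21, IPD-IMGT/HLA reference protein
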
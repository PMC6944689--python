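gene_id	chrom	start	end	biotype	r	p_value
NEIGHBOR01	chr20	27644184	27651468	protein_coding	0.931735258	7.934893185e-38
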
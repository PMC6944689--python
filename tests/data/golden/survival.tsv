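gene_id	n_high	n_low	chi_square	p_value	bh_q
PLANTED01	34	34	9.063957233	0.002606971625	0.007820914876
PLANTED03	34	34	0.006970867041	0.9334605622	0.9334605622
PLANTED02	34	34	0.6471005904	0.4211512054	0.6317268081
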
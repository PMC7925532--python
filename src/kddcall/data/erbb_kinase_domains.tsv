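gene_id	chrom	kd_start	kd_end
EGFR	chr7	55201385	55237880
ERBB2	chr17	37972200	38012490
ERBB3	chr12	56595127	56633770
ERBB4	chr2	212259688	212310309
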
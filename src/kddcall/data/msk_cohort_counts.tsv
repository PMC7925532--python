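# EGFR/ERBB2 kinase-domain-duplication counts across a 40,165-sample
# prospective matched tumor-normal panel cohort.  The "other" row aggregates
# tumor types not broken out individually (no KDD events) so the overall
# denominator is preserved.
tumor_type	gene_id	kdd_positive_count	total_samples
glioma	EGFR	10	1735
glioma	ERBB2	0	1735
breast	EGFR	1	5614
breast	ERBB2	2	5614
NSCLC	EGFR	3	5986
NSCLC	ERBB2	1	5986
bladder	EGFR	0	1266
bladder	ERBB2	1	1266
GYN	EGFR	0	1600
GYN	ERBB2	1	1600
other	EGFR	0	23964
other	ERBB2	0	23964
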
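# ERBB-family kinase-domain-duplication counts across a 237,701-sample
# pan-cancer comprehensive-genomic-profiling cohort (hybrid-capture panel).
# total_samples is the per-tumor-type denominator and repeats on each gene row.
# The "other" row aggregates tumor types not broken out individually so that
# per-gene grand totals (EGFR 443, ERBB2 217, ERBB3 92, ERBB4 47; 799 overall)
# and the overall denominator are preserved.
# GI = upper gastrointestinal cancer; GYN = gynecological; HNC = head and neck.
tumor_type	gene_id	kdd_positive_count	total_samples
glioma	EGFR	222	9381
glioma	ERBB2	1	9381
glioma	ERBB3	4	9381
glioma	ERBB4	0	9381
NSCLC	EGFR	70	48699
NSCLC	ERBB2	18	48699
NSCLC	ERBB3	11	48699
NSCLC	ERBB4	10	48699
GI	EGFR	40	11822
GI	ERBB2	44	11822
GI	ERBB3	3	11822
GI	ERBB4	2	11822
melanoma	EGFR	2	6837
melanoma	ERBB2	0	6837
melanoma	ERBB3	5	6837
melanoma	ERBB4	0	6837
prostate	EGFR	4	8203
prostate	ERBB2	1	8203
prostate	ERBB3	1	8203
prostate	ERBB4	4	8203
bladder	EGFR	6	4886
bladder	ERBB2	3	4886
bladder	ERBB3	2	4886
bladder	ERBB4	2	4886
GYN	EGFR	10	26873
GYN	ERBB2	40	26873
GYN	ERBB3	34	26873
GYN	ERBB4	16	26873
breast	EGFR	27	24467
breast	ERBB2	52	24467
breast	ERBB3	13	24467
breast	ERBB4	7	24467
HNC	EGFR	2	5380
HNC	ERBB2	7	5380
HNC	ERBB3	1	5380
HNC	ERBB4	0	5380
other	EGFR	60	91153
other	ERBB2	51	91153
other	ERBB3	18	91153
other	ERBB4	6	91153
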
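# Methods

## Problem and scope

`kddcall` detects intragenic tandem duplications of the tyrosine-kinase-
domain (TKD)–encoding exons of ERBB-family genes in targeted hybrid-capture
panel data. Two evidence channels are modelled, mirroring how clinical
pipelines see such events: per-exon depth of coverage (copy-number channel)
and discordantly mapped read pairs (rearrangement channel). The package
does not perform genome-wide CNV segmentation, BAM-level realignment, or
split-read base-pair breakpoint refinement; evidence enters at the
exon-depth and anchor-coordinate level.

All coordinates are 0-based half-open internally (BED convention);
conversion to 1-based coordinates happens only when writing VCF. One
canonical transcript per gene is modelled; exon ordinals follow transcript
(strand-aware) order, so ordinal 1 of a minus-strand gene is the
genomically last exon.

## Gene models and the 70% criterion

A `GeneModel` holds ordered exons plus the genomic interval of the kinase
domain. The packaged annotation covers EGFR, ERBB2, ERBB3 and ERBB4 with
hg19-like but synthetic coordinates: exon counts and the location of the
TKD within the transcript are canonical (EGFR: 28 exons, TKD intersecting
exons 18–25; ERBB4 on the minus strand) while the exact base positions are
generated. Users supply real annotation via GFF3/BED12 plus a
kinase-domain TSV.

"Involvement" of the kinase domain by a set of intervals is measured at
base level over **exonic** kinase-domain bases: panels only observe
coverage on exons, so intronic KD bases carry no signal and are excluded
from numerator and denominator alike (`mode="genomic"` is available).
This is a documented choice; counting whole exons or genomic bases would
shift the effective threshold on partial events.

## Coverage caller

Given tumor and unmatched-normal exon depths over one gene:

1. zero depths are replaced by `pseudo_depth` (default 1 read) so ratios
   stay finite; positive depths are never perturbed, so noise-free signals
   are exact (a clonal, pure single-extra-copy duplication yields
   fc = log2(3/2) to machine precision);
2. each sample is divided by its own median exon depth, removing
   library-size differences (the caller is invariant to scaling either
   sample by a positive constant) — note this also flattens whole-gene
   amplification, which is the desired behaviour since amplification is
   not KDD;
3. fc = log2(tumor_norm / normal_norm) per exon (a linear-scale variant is
   configurable);
4. the fc profile is clustered by **exact 1-D 2-means**: optimal 2-means
   clusters of scalars are contiguous in sorted order, so scanning the
   n − 1 sorted split points with prefix sums finds the global SSE optimum
   deterministically. SSE ties keep the smallest low cluster; equal values
   straddling the split are assigned by stable sort order. Profiles with
   range below `degenerate_tol` (default 0.05 in log2 units) are declared
   flat: this prevents the clusterer from manufacturing splits out of
   pure noise;
5. the sample is positive iff the clustering is non-degenerate, the
   difference of cluster medians is ≥ `min_median_diff` (default 0.4),
   and the high cluster's exons either cover ≥ `min_kd_overlap` (default
   0.70) of the exonic kinase domain or contain every kinase-domain exon.
   Both thresholds are inclusive. An `exclude_whole_gene` guard (default
   on) additionally requires a non-empty low cluster.

The 0.70 / 0.4 defaults are the established operating point for this
analysis; on the log2 scale the 0.4 threshold sits below the clonal
single-copy signal of 0.585, leaving headroom for purity and subclonality
(expected ratio (2 + purity · clonal_fraction · extra_copies)/2). The
"median cluster fold change difference" is interpreted as the difference
of the two cluster medians.

## Breakpoint caller

Concordant pairs are discarded; chimeric pairs (both mates anchored) with
both anchor midpoints inside the gene span ± `flank` (default 5 kb, to
admit promoter/UTR breakpoints) are clustered by single linkage: two pairs
join iff their left-anchor midpoints and right-anchor midpoints are each
within `window` (default 300 bp, of the order of an insert size). Single
linkage is order-independent and avoids fixed-bin boundary artifacts.
Cluster consensus breakpoints are the per-side medians of anchor
midpoints, rounded to integers. Semi-mapped pairs (one confidently mapped
mate) attach to an existing cluster when their anchored midpoint lies
within `window` of either consensus and add support; they never seed a
cluster. Clusters with total support below `min_support` (default 2,
either evidence class) are suppressed.

A cluster is interpreted as a tandem duplication only with the everted
signature (left anchors reverse, right anchors forward — reads spanning a
junction that joins the duplicated segment's end back to its start);
forward/reverse clusters are rejected as deletion-like, same-strand as
inversion-like. The duplication is KDD-positive iff
`bp_left < kd_start` **and** `bp_right > kd_end` (strict flanking: a
breakpoint on the kinase-domain boundary counts as disrupting) and both
breakpoints are intragenic (gene span ± flank). Window, support and flank
defaults are package choices — the clinical pipelines this emulates do not
publish theirs — and are configurable.

## Consensus

Coverage-positive and breakpoint-positive → *confident*; exactly one →
*candidate*; neither → *negative*. The tier lattice is monotone in each
input. This fixed policy stands in for the manual review step used in
clinical practice; it is deliberately deterministic.

## Synthetic data generator

The generator emulates the statistical structure the callers assume, at
the level they consume:

- **Exon depth**: negative binomial with mean μ and variance μ + d·μ²
  (dispersion d = 0 degenerates to the deterministic mean). Default
  baseline 500× matches deep clinical panels. Squared CV at depth μ is
  1/μ + d; `dispersion_for_cv` inverts this. Tumor exons inside the
  duplication are scaled by (2 + purity · clonal_fraction · extra_copies)/2,
  prorated by the fraction of the exon inside the event.
- **Read pairs**: `n_support` junction pairs in everted orientation whose
  anchor midpoints scatter as round(Normal(breakpoint, jitter_sd)); a
  configurable fraction (default 0.8) is chimeric, the rest semi-mapped
  with only one anchored side; concordant background pairs are uniform
  over the gene. Default jitter 30 bp reflects anchor-level breakpoint
  uncertainty at ~100 bp reads.
- **Cohorts**: each sample is KDD-positive with its row's prevalence
  (independent Bernoulli), or exactly round(n·p) positives in
  expected-count mode, which exists so that fixed published counts can be
  reproduced deterministically. Positives carry a duplication spanning the
  gene's kinase-domain exons with a 200 bp margin.

Everything is reproducible from seeds; identical configuration yields
byte-identical output files.

What the generator does **not** model: GC and capture-efficiency bias,
correlated noise across neighbouring exons, panel-of-normals structure,
multi-copy or nested rearrangements, off-target gene breakpoints, or
base-level reads. Passing recovery tests therefore demonstrates
correctness of the callers' decision logic under the stated noise model,
not expected performance on real tumor data.

## Prevalence and enrichment

Calls aggregate into tumor-type × gene tables with per-tumor-type
denominators; one call per sample × gene counts once. Percentages are
rounded half away from zero at caller-chosen precision (published tables
mix 1- and 2-decimal reporting). Enrichment of a gene's KDD burden in one
tumor type versus the rest uses the two-sided Fisher's exact test
(point-probability convention: summing hypergeometric probabilities of
tables no more likely than observed; SciPy's implementation, with the
sample odds ratio a·d/(b·c) reported as 0/∞ explicitly at zero cells).
The test suite checks the p-values against an exact-rational enumeration
oracle to 1e-12. No multiple-testing correction is applied across tumor
types.

The packaged count table reproduces a published pan-cancer incidence
table: nine named tumor types plus an aggregate remainder row so that
per-gene grand totals (443/217/92/47 of 237,701; 799 events overall) are
preserved. One published percentage (EGFR in NSCLC, printed as 1.4%) is
inconsistent with its own printed counts (70/48,699 = 0.14%); the package
reports the value computed from the counts and does not reproduce the
printed figure.

## Operating characteristics and known limitations

`scripts/acceptance.py` measures caller operating characteristics on
200-positive / 200-negative seeded cohorts. At the reference conditions
(single extra copy over the kinase-domain exons, purity 1, 500× depth,
depth CV 10% in both tumor and normal) the breakpoint caller attains
recall 1.0 with zero calls on background-only samples, and the coverage
caller attains recall ≈ 0.9 at false-positive rate ≤ 0.05.

The coverage-caller recall ceiling is intrinsic to the decision rule at
that noise level, not an implementation artifact: with both samples at
depth CV 10%, per-exon fc noise has sd ≈ √2 · 0.1/ln 2 ≈ 0.20, so the
difference of cluster medians (8 kinase-domain vs. 20 other exons for
EGFR) has sd ≈ 0.11 even under oracle-perfect exon assignment, putting
the 0.4 threshold only ≈ 1.7 sd below the 0.585 signal; 2-means
assignment errors consume the remainder. The 2-means step itself is
verified globally optimal against exhaustive 2-partition enumeration.
Recall rises quickly with lower dispersion, higher depth, or wider
duplications. Sample sizes in the recovery runs (200 per arm, n = 9,381
for the expected-count cohort) are the package's chosen defaults for a
stable estimate at interactive runtimes.

Other limitations: one transcript per gene (no isoform resolution); no
liftover between genome builds; semi-mapped evidence is one-sided by
construction and cannot nominate novel breakpoints; the consensus tier is
a fixed policy, not a learned reviewer model.
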
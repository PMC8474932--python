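# Methods

## Problem setting

Single-cell combinatorial-indexing Hi-C yields, per cell, a sparse list of
chromatin contact pairs; with SNP-bearing reads each pair can be assigned to
its parental haplotype. During X inactivation one chrX homolog (the Xi)
adopts a bipartite conformation — two superdomains of enriched long-range
contacts separated at the *Dxz4* hinge, with depleted TAD-scale (mid-range)
structure. At 50–5,000 contacts per allele, full contact maps are
uninformative per cell; the analysis therefore works on contact decay
profiles (CDPs) and scalar statistics derived from them, calibrated against
chr1 as a within-dataset null. Matched sci-RNA-seq / sci-ATAC-seq allelic
UMI counts give the transcriptional side of the same process.

## Contact processing

A contact record is (cell barcode, chrom/pos for both ends, haplotype tag).
Allelic segregation is per pair: a pair is hap1/hap2 when at least one end
carries a SNP particular to exactly one haplotype, ambiguous when no end
carries any (usable only non-allelically), and a conflict when both
haplotypes have evidence (discarded everywhere). Cell QC requires ≥ 1,000
valid pairs, a cis:trans ratio ≥ 1 (trans = 0 passes: the test is a lower
bound) and ≥ 95% species purity — the purity filter abstracts the
human-spike-in doublet control; alignment itself is upstream of this
package. Informative contacts are interchromosomal pairs plus
intrachromosomal pairs spanning > 1 kb; positions are single mapped
coordinates (0-based) and distances are |pos_a − pos_b|.

## The CDP grid

143 half-open bins [2^x, 2^(x+0.125)) with x = 10 … 27.750 (first edge
1024 bp). Bin assignment is computed in log2 space with a 1e-9 exponent
tolerance and is tested to agree exactly with a linear edge scan, including
for integers adjacent to every edge. Profiles are computed per (cell,
chromosome, allele) and scale-normalized to proportions — per
chromosome-allele, not per whole cell — so a profile is a distance
distribution invariant to coverage; this keeps downstream rank statistics
comparable across cells of very different depth. Rebinning sums
non-overlapping groups of 10 fine bins; the trailing 3 fine bins cover
separations ≥ 2^27.5 bp (~1.9×10^8, longer than any mouse chromosome) and
are dropped, giving 14 coarse bins. Heatmap z-scaling standardizes each bin
column across cells with the population SD; constant columns map to 0.

## Bipartite-Xi statistics and thresholds

The LMD of a normalized profile is the summed proportion in the long-range
window minus that in the mid-range window. The window endpoints are the
grid edges nearest the nominal values: mid = [2^16.375, 2^20) ≈ 85 kb–1.05 Mb
(fine bins 51–79), long = [2^22.625, 2^26.375) ≈ 6.5–87 Mb (bins 101–130);
both windows are exact unions of fine bins, so no partial-bin weighting
arises. ΔLMD = LMD(hap1) − LMD(hap2); the Spearman ρ between the homologs'
rebinned CDPs uses average ranks for ties and is undefined (NaN, no call)
for constant vectors.

Thresholds are nearest-rank (ceiling) empirical quantiles of the chr1 null:
the (1 − FPR) quantile of |ΔLMD| (or |TAE log2 ratio|), the FPR quantile for
ρ. Calls use strict inequality, so at most ⌊FPR·n⌋ null values can be
called. Nearest-rank was chosen over interpolated quantiles for
reproducibility without interpolation ambiguity. Cells failing per-allele
coverage (≥ 100 contacts per allele per chromosome for Patski-like data,
≥ 50 otherwise) are "no call" and never counted as negatives; reported
proportions use callable cells as denominators.

A classifier calibrated to a known FPR inflates raw positive proportions by
(1 − f)·FPR. Where recovered fractions are compared against generator
truth, the package reports the Rogan–Gladen-corrected estimate
f̂ = (p̂ − FPR)/(1 − FPR) (valid when sensitivity ≈ 1, which holds at the
strong effect sizes used) alongside the raw rate, with a Clopper–Pearson
95% interval mapped through the same linear correction.

## Cell-cycle staging

Profiles are non-allelic (ambiguous pairs included), aggregated over
autosomes only, restricted to the 58 fine bins fully inside 50 kb–8 Mb, and
normalized. k-means with a Spearman correlation distance is not standard;
the operative definition here: rank-transform each profile, center and
unit-normalize, then Euclidean k-means (k-means++, fixed seed) — squared
Euclidean distance between such vectors is an affine function of
(1 − Spearman ρ). Rows are canonically sorted before clustering so results
are invariant to input order at a fixed seed. The cluster with the highest
mean mitotic-band fraction (fraction of autosomal informative contacts in
[2, 12) Mb; short-range is [1 kb, 2 Mb) — both band definitions are package
decisions, config-exposed, following the single-cell Hi-C cell-cycle
literature) is labeled mitotic; remaining clusters are ordered by
decreasing short-range fraction as interphase progression.

## Contact score

For a binned cis matrix (500 kb default), the raw score of bin c is the
mean over all cells (i, j) with i ≤ c ≤ j and j − i ≤ arm/resolution
(arm 20 Mb), after adding a pseudocount of 1 to every bin; truncated
windows at chromosome ends divide by the cells actually included, and the
diagonal cell of the central bin is counted. Scores are normalized as
log2(score / chromosomal mean) — the mean taken over valid bins only — with
the first and last 10 Mb excluded, missing bins (zero marginal coverage)
cubic-spline interpolated (linear below 4 anchors) for smoothing and
restored to NaN afterwards, and a Savitzky–Golay filter (window 5, degree 2)
applied. Dip location searches local minima (plateaus of equal values count
once; track boundaries never qualify) nearest a locus within a window;
depth is measured against the nearest flanking local maxima. The score is
computed cis-only, consistent with a diagonal-sliding window.

## Allelic skew

Features are kept when covered on at least one allele in ≥ 10 cells; cells
when their chr1 and chrX allele totals reach 10 UMIs. The per-allele
reading of the cell filter (each allele ≥ 10) is the general contract; for
call-time filtering the combined reading (both alleles together ≥ 10) is
used instead, since a fully silenced allele (0 UMIs) must remain callable —
both modes are exposed. The skew statistic is
log2((hap1 + 1)/(hap2 + 1)); the pseudocount keeps silenced alleles finite.
A cell is called silenced when |ratio| strictly exceeds the chr1-derived
10%-FPR threshold; the sign identifies the silenced homolog (negative ⇒
hap1 silenced) and the homolog with the higher total is the active X. The
threshold is always recomputed from the supplied chr1 null rather than
hard-coded (a published value of ≈ 1.2 serves only as a regression
reference). The ATAC path mirrors the RNA path with peaks as features and a
500-UMI per-cell pre-filter. The X:A ratio is the per-cell mean over
qualifying chrX genes divided by the mean over qualifying autosomal genes
(qualifying = expressed in ≥ 10 cells).

## Synthetic data generator

Distances are sampled by inverse CDF on the decay law discretized over the
143-bin grid (mass ∝ ∫ d^(−α) per bin, truncated at the chromosome length),
then placed uniformly within the bin — aligning generator resolution with
analysis resolution so effect sizes are directly interpretable on the
statistics. Defaults: chr1 = 195 Mb, chrX = 171 Mb; per-allele coverage
log-uniform 50–5,000; α = 1 (each log bin carries equal mass, the canonical
single-cell Hi-C regime); mitotic cells multiply 2–12 Mb mass by 8;
the bipartite modification multiplies mid-range mass by 0.5 and long-range
mass by 4 on the designated Xi homolog only (suppressed in mitotic cells,
where condensation erases the superdomains), renormalizing so total
probability is conserved exactly; the boosted share of long-range pairs is
placed within a single superdomain around a hinge at 44% of chrX length.
Population composition (bipartite fraction per time point, 3% mitotic,
Xi-allele skew) is allocated deterministically by rounding, with labels
assigned under the seed. Allelic UMI counts are gamma-Poisson (negative
binomial marginally): count ~ Poisson(rate_gene × depth_cell × m) with
log-normal gene rates (mean 0.5 UMIs/gene/allele/cell over 300 chr1 + 200
chrX genes), gamma depth (shape 5), m = 1 for active alleles and 0.02
(residual escape expression) for the silenced Xi allele; male cells carry
zero hap2 chrX counts.

What the generator does **not** emulate: TAD/loop/compartment structure
(so chr1 allelic rebinned CDPs correlate near 0 under rank statistics,
whereas real chr1 homologs correlate near 1 — the ΔLMD classifier is
unaffected, but the Spearman-mode classifier has less power on synthetic
than on real data), trans contacts (off by default; a uniform trans
fraction exists for QC testing), position-dependent coverage, barcode
collisions, and escape-gene heterogeneity. Passing tests therefore
demonstrate correctness and calibration of the statistics under the stated
decay model, not biological realism of contact maps.

## Benchmark problem sizes and numerical notes

The benchmark experiments use 2,000 cells (calibration; 1,000/1,000
train/test split), 100 cells per time point over 5 time points (recovery),
100 cells across 4 archetypes at 250–2,500 contacts per allele (cell
cycle; QC-passing cells carry ≥ 1,000 pairs, hence the raised floor), and
60 Hi-C + 100 RNA cells per time point (lag). Note the calibration
estimate's spread exceeds pure binomial noise: the threshold is itself
estimated from 1,000 training cells, roughly doubling the SD of the
held-out call rate around the nominal 10% (≈ 1.5 points rather than 0.95).
Degenerate inputs are handled explicitly throughout: zero-coverage profiles
flag low-coverage and propagate NaN statistics to "no call"; constant
vectors are undefined for rank correlation; fewer than k distinct
cell-cycle profiles raise rather than silently merging clusters; empty
groups are omitted from proportion tables with a warning. Seeds enter only
through `numpy.random.default_rng`, and every generator is bit-reproducible
given its seed.
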
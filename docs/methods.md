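# Methods

## Problem and model

`sexscan` locates and characterizes *young homomorphic* sex-linked
regions — chromosome segments co-inherited with a recently established
sex-determining locus, where the X and Y (or Z and W) have not yet
diverged enough to be seen in coverage or assembly. In such a system the
signature of the sex-linked region (SLR) under male heterogamety is:

- every fixed X/Y difference site is **heterozygous in males and
  homozygous in females**, so the SLR shows a dense excess of
  male-het/female-hom sites and strongly negative F_IS in males;
- allele frequencies differ between the sexes (the Y allele occurs only
  in males at frequency 1/2), elevating between-sex **F_ST** to about
  1/3 per fixed site at large n;
- every fixed difference is perfectly associated with phenotypic sex, so
  a **genome-wide association scan** with sex as a binary trait marks
  the region with Bonferroni-significant SNPs;
- the pseudoautosomal region (PAR) shows none of these, so the PAR/SLR
  boundary appears as a change point in all three window tracks.

The pipeline computes the three tracks in 50 kb sliding windows with a
25 kb step, calls heterogamety from the balance of male-het versus
female-het significant sites, detects and excludes phenotypically
mislabeled (sex-reversed) individuals, recomputes the tracks, segments
them by change-point analysis, and classifies segments PAR / SLR /
undetermined. For fully sex-linked genes it reconstructs X and Y coding
haplotypes and estimates synonymous divergence Ks by the Nei–Gojobori
(1986) codon-counting method, which dates the recombination arrest.

## Statistics

**F_IS** = 1 − Ho/He per SNP, with He = 2p̂(1−p̂) from the sample allele
frequency, no small-sample correction (an option exists). He = 0 gives a
missing value.

**F_ST** uses the Weir–Cockerham (1984) per-site estimator with the two
sexes as populations; window values are the arithmetic mean of per-site
estimates by default (negative estimates retained), with a
ratio-of-sums "weighted" variant for sensitivity checks. Sites need at
least two called genotypes per sex.

**Association test.** The default is a two-sided Fisher exact test on
the 2×2 allelic table (alleles × sex), with a genotypic chi-square
option. A kinship-corrected mixed model would be preferable on real
pedigreed cohorts; the exact test assumes unrelated individuals, which
the synthetic cohorts satisfy by construction, and is deterministic and
assumption-free at any count. Genome-wide significance is Bonferroni:
alpha / number of tested SNPs (0.05 by default). Under the null the
exact test is conservative (discrete tables), so its rejection rate at
alpha = 0.05 sits near 0.04 with ~60 individuals; the genotypic
chi-square is asymptotically calibrated. The calibration test asserts
two-sided agreement for the chi-square and non-anticonservativeness for
the exact test.

**Heterogamety.** Among Bonferroni-significant sites, a site is
"male-het" when ≥ 80% of included males are het and ≥ 80% of included
females are hom (mirror for "female-het"). The call is XY when the
male-het share of classified sites is ≥ 0.8 and an exact binomial test
against 0.5 rejects at 0.01; ZW mirrored; otherwise undetermined. These
defaults separate a 59% share (undetermined) from a ~99.6% share (XY).

**Sex reversals.** Individuals whose genotypes at the 100 most strongly
sex-associated SNPs match the opposite sex's expected pattern (het
where hom is expected and vice versa) in ≥ 90% of non-missing sites are
flagged and excluded; detection is a single pass, and downstream
statistics are recomputed on the pruned cohort. Ranking ties break by
(P, chromosome, position) for determinism. The 0.9 match fraction
operationalizes "matches at almost all sites"; it is configurable.

**Change points.** Binary segmentation under a Gaussian model in which
each segment has its own mean *and* variance: segment cost is
n·log(max(σ̂², 1e-8)), splits are accepted greedily while the
likelihood gain exceeds the penalty, up to three change points per
track. The penalty default ("mbic") is 3·log(n) — three extra
parameters (mean, variance, location) per change point; a numeric
override exists, and the exact MBIC segment-length terms are omitted
for simplicity. The cost depends on the data only through segment
variances, so change-point locations are invariant to adding a constant
or positive scaling (up to the variance floor); the first accepted
split coincides with the exhaustive optimal single split, which the
tests verify. The variance floor (1e-8) makes constant series yield no
change points.

**Region calling.** Candidate boundaries from the F_ST, −log10 P and
male-het-density tracks are merged when within one window step
(overlapping windows make a point estimate necessary; the boundary is
placed at the midpoint of the adjacent window centers). A segment is
SLR when it contains ≥ 1 genome-wide-significant SNP and its mean F_ST
and het density both exceed the 90th percentile of the background
windows; adjacent segments of equal status are coalesced (extra change
points inside a homogeneous region are splits, not boundaries); non-SLR
segments abutting an SLR are PAR, everything else undetermined. The
background reference for the percentile is the set of windows with no
significant SNP — with a single candidate chromosome whose SLR spans
most windows, an all-window quantile would sit inside the SLR's own
distribution; pass `background_thresholds` when genome-wide tracks are
available.

**X–Y divergence.** Genes in which every variable CDS site is het in
all included males and hom (for one allele) in all included females are
fully sex-linked; the female allele is the X allele and the
male-specific alternate the Y allele. X and Y CDSs are rebuilt from the
reference (strand-aware, exons concatenated per gene), and NG86
proceeds per codon: potential synonymous site fractions averaged over
the two sequences (changes to stop codons count as nonsynonymous in the
potential-site denominators), observed differences in multi-difference
codons averaged over all mutational pathways with pathways through
stops excluded (a flag counts them instead; if every pathway hits a
stop the full set is used), codons with ambiguous bases excluded
entirely, and the Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3)
applied, undefined (missing) at p ≥ 3/4. The summary Ks is the
unweighted mean over genes (per-gene averaging rather than
concatenation, matching gene-level reporting).

**Expression side.** TPM columns sum to 1e6; quantile normalization
forces every sample to the mean sorted distribution with average-tie
handling; τ = Σ(1 − x_i/max)/(n−1) after dropping genes below 1 TPM in
every tissue; a gene is tissue-specific when τ ≥ 0.8 and its top tissue
ranks within its top three normalized values (ties at rank three are
all included); tissue bias is TPM ≥ 2× the mean of the other tissues at
the same stage (inclusive); enrichment per chromosome is a one-sided
(greater) Fisher exact test with raw-P significance marks at 0.05/0.01
(no multiple-testing correction by default, since enrichment is
reported descriptively; a BH option would be a one-line addition).

**Inversion genotypes.** f = supporting/informative read pairs:
f ≤ 0.25 homozygous reference, 0.25 < f < 1 heterozygous, f = 1
homozygous inverted. The boundary conventions (f exactly 0.25 → homRef,
f = 1 → homInv) are flagged in the output table. Evidence extraction
from alignments is out of scope; the module consumes a pre-tabulated
evidence TSV.

## Synthetic data

The generator emulates a diploid cohort genotyped at biallelic SNPs on
one chromosome carrying PAR(s) and an SLR:

- **Background polymorphism**: site positions by a Poisson process;
  `theta` (default 3.65e-4/bp expected heterozygosity) converts to a
  SNP density of theta/0.365 ≈ 1 SNP/kb given allele frequencies
  uniform on [0.05, 0.95] (chosen so the MAF > 0.05 filter is
  non-trivially exercised); genotypes in Hardy–Weinberg proportions.
- **Fixed X/Y differences** inside the SLR at per-bp rate
  `xy_divergence` (default 1e-4): het in genotypic males, hom-ref in
  genotypic females; REF is the X allele.
- **Sex reversal** flips an individual's genotypic sex relative to its
  phenotypic label with probability `reversal_rate`.
- **Leak** (rare X–Y exchange) gives a genotypic male a female-like
  genotype over a contiguous terminal SLR block (single-crossover
  geometry, uniform block start) with probability `leak_rate`.
- **Depth** per individual per 50 kb bin is Poisson(`mean_depth`),
  halved for males over an optional terminal Y-degenerate sub-interval,
  which drives the normalized male/female coverage ratio to 0.5.

Default geometry is the study-scale scenario: 30 males + 29 females,
26.1 Mb chromosome, PAR = first 1.28 Mb (4.9%), SLR the rest (95.1%).
Individuals are unrelated; no linkage disequilibrium, genealogy, or
linked selection is simulated, and sites are exchangeable given their
class. Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the assumed architecture, not robustness to
family structure, LD between background sites, or calling artifacts in
real data. The RAD generator plants markers present (depth ≥ threshold)
only in one sex over a background of sex-independent presence; the
expression generator plants fold-boosted genes over a log-normal
background.

The gene-level generator (`simulate_sexlinked_genes`) builds a small
contig of stop-free single-exon CDSs (30% minus-strand) and plants X/Y
differences uniformly over CDS positions at a per-bp rate, re-drawing
any substitution that would create a stop on either haplotype. With
uniform per-bp substitution the expected synonymous divergence per
synonymous site equals the planted rate, so mean Ks is directly
comparable to it. Because genes without variable sites cannot be
assessed (the same conditioning as in the real selection rule), the
recovery experiments use 2400 bp CDSs — a typical concatenated gene
CDS — so that the expected per-gene mutation count (≈ 5–14 at rates
0.002–0.006) makes the zero-variant exclusion negligible; at much
shorter CDSs that conditioning visibly inflates the conditional mean.

## Problem sizes and numerical choices

The full study-scale scenario (26.1 Mb, 59 individuals, ~28,000 SNPs)
runs once in the acceptance script and once in the test suite (~2 s);
other tests use 1.5–8 Mb chromosomes. The heterogamety experiment uses
100 seeds at 1.5 Mb; reversal precision/recall pools 8 seeds at 2 Mb;
Ks recovery uses 300 and 200 genes at planted rates 0.002 and 0.006.
Association P-values are cached by table counts (sites with equal
counts share a P), making the exact scan linear in distinct tables.
Missing genotypes are excluded site-wise everywhere (no imputation).
Internal coordinates are 0-based half-open; VCF (1-based) and GFF3
(1-based inclusive) convert at the I/O boundary.

## Known limitations

- The association test ignores relatedness; on family-structured
  cohorts it will be anticonservative. Use a mixed model upstream and
  feed its P-values in if needed.
- Region classification depends on a background reference; on input
  restricted to the candidate chromosome the no-significant-SNP proxy
  can be biased if significant SNPs leak outside the true SLR.
- Boundary placement is limited by window geometry (±1–2 window steps).
- NG86 underestimates divergence at saturation and applies no
  transition/transversion or codon-frequency weighting (GY94-style
  maximum likelihood is out of scope).
- The leak model is a single terminal crossover; interstitial gene
  conversion tracts are not simulated.
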
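# Methods

`metaferm` re-implements, as a tested library and CLI, the bespoke
computations used to analyse metatranscriptome time series from in-vitro
batch fermentations of isomalto/malto-polysaccharides (IMMPs) with human
faecal inoculum: taxonomic assignment of assembled genes, differential
expression over time, detection of co-occurring taxa and recurring gene
expression patterns, functional profiling, and cross-project comparison.
Because the real datasets require external sequence databases and
hundreds of millions of reads, correctness is established on synthetic
data with planted ground truth plus independent oracles, not by
reproducing the original study's numbers.

## Taxonomic assignment (banded LCA)

Each gene's alignment hits pass three filters before the lowest common
ancestor (LCA) is taken:

1. E-value ≤ 1e-4;
2. bit-score strictly greater than 50 and alignment length strictly
   greater than 100 nt (the wording "exceeded" / "more than" is taken
   literally, so a hit at exactly 50 bits or exactly 100 nt is removed);
3. a top-band filter keeping hits whose band statistic *b* satisfies
   *b* ≥ (1 − f)·max(*b*) with f = 0.10.

The band statistic is the bit-score for the nucleotide tiers (the MEGAN
top-percent convention) and the percent identity for the protein tier.
The phrase "did not deviate more than 10% from the longest hit" admits a
length reading as well, so the criterion is a configuration enum
(`BITSCORE`, `LENGTH`, `IDENTITY`) with bit-score as the default.
Assignment cascades through up to three tiers (primary nucleotide search,
fallback nucleotide search, protein search against an orthology
database); the first tier with a non-empty filtered hit set decides, and
hits to taxa absent from the taxonomy are dropped with a warning.  The
LCA itself is the deepest node ancestral-or-equal to every hit taxon; it
is verified exhaustively against a brute-force lineage-intersection
oracle on random taxonomies.

For display and downstream grouping, assignments are rolled up to genus:
genes assigned at or below genus report the genus, genes assigned above
genus report "unclassified *lowest-assigned-taxon*".

## Differential expression (TMM + DEGES iteration)

Between-sample normalization follows the trimmed mean of M-values (TMM):
for each sample against a reference (by default the sample whose
75th-percentile count share is closest to the mean), log2 ratios M and
log intensities A are computed over genes positive in both samples; the
30% most extreme M (each tail) and 5% most extreme A are trimmed, and the
remaining M are averaged with inverse delta-method variances and
exponentiated.  Factors are rescaled to geometric mean 1.  All-zero genes
are removed first (they are inert but would shift the reference rule).
The implementation agrees with edgeR's `calcNormFactors(method="TMM")`
to ~1e-6 on random tables; that cross-check runs via Rscript in the test
suite as an independent oracle.

Contrasts are every later time point versus t0 within each condition.
The per-gene test pools replicates: conditional on the pooled total
n = k_A + k_B, the group-A count is Binomial(n, s_A/(s_A+s_B)) under the
null, with s the summed effective library sizes; the two-sided p-value
sums all outcome probabilities not exceeding the observed one.  This
conditional-binomial primitive (`exact_count_test`) is enumerable and is
verified against exhaustive enumeration.

Fermentation counts are over-dispersed (negative binomial, variance
μ + αμ²), and a dispersion-0 conditional test is badly anticonservative
on such data.  The pipeline therefore widens the conditional law to a
beta-binomial by default: pooling R replicates of an NB gene gives a
gamma shape of R/α per group, so k_A | n ~ BetaBin(n, R_tot·π,
R_tot·(1−π)) with R_tot the total replicate count over both groups and α
a common dispersion estimated by moments from within-replicate-group
scatter (E[s²] = c·m + α·m², pooled over genes and groups, with an
E[m²] = μ² + Var/R correction).  With α̂ → 0 the test reduces to the
plain binomial.  The switch (`DeParams.overdispersion`) defaults to on
because the calibrated test is the only defensible default for the data
this pipeline targets; setting it off recovers the pure binomial.

The iteration implements the DEGES idea: (1) TMM on the current gene
set; (2) test all genes; (3) flag candidates at a permissive gate
(Benjamini–Hochberg q < 0.1); (4) recompute TMM on unflagged genes;
repeat until the factors move less than 1e-6 or 36 iterations (the cap
mirrors the original analysis; in practice convergence takes 2–6
iterations).  The final call is q < 0.01 in at least one contrast.  Known
limitation: replicates are pooled rather than modelled, so
between-replicate variability enters only through the moment dispersion
estimate.

## Taxon co-occurrence clustering (k-means stability)

Genera enter the clustering if their mean count per gene over all genes
and samples is ≥ 10, or their share of all reads exceeds 1% in at least
one condition.  Their relative-count profiles (genus sum / sample total
over selected genera) are clustered with k-means for k = 1..20, 50
restarts per k (scipy's k-means engine with k-means++ starts).  "Cluster
support" is not defined in the original description, so it is implemented
as the mean pairwise Adjusted Rand Index over the 50 restart partitions —
a bounded, k-comparable stability surrogate.  The chosen k maximizes
support; k = 1 and k = n_rows are reported but excluded from the choice
(both are trivially stable), and ties break toward the smaller k.  The
reported partition is the restart with the lowest within-cluster sum of
squares at the chosen k, relabelled canonically (order of first
appearance) for deterministic output.  A clustergram table records, per
k, each cluster's size, mean level and plurality parent at k − 1.

## Gene pattern mining (DBSCAN + tau selection)

Within each selected genus, only differentially expressed genes are
clustered.  Rows are normalized to shares (divide by row sum; an
alternative divide-by-max is available), all-zero rows removed.
Euclidean DBSCAN runs with minpts = 3 over an epsilon grid of 1%–50% of
the maximum pairwise distance in 1% steps (the source describes epsilon
"varied in percentages" without a range).  Each clustering is scored by
the tau concordance index: over all (within-pair, between-pair) distance
comparisons, tau = (concordant − discordant)/(|W|·|B|), ties counting
zero; the implementation is verified against a brute-force double loop.
The epsilon with the best tau is chosen; among ties, the labeling with
the fewest noise points wins, then the smaller epsilon.  A per-genus
manual override is available, mirroring the one case in the original
analysis where a suboptimal tau gave visually better separation.

Clusters are classified into trajectory classes from (condition, time)
cell means of the row shares.  A cell is "expressed" when its mean share
over replicates is ≥ θ = 0.15 (no numeric cutoff is given in the source;
θ is configurable).  T0_ONLY: expressed at t0 and nowhere later.
CONTROL_LATE: expressed only in the substrate-free control at 48 h.
UP_LATE: silent at t0, expressed later, with non-negative rank
correlation between share and time.  Otherwise OTHER; noise genes carry
no class.  The cluster label is the majority vote of its members.  Note
that θ = 0.15 is only meaningful when the design has at most ~6
(condition, time) cells — with 20+ cells even a perfectly monotone gene
spreads below θ everywhere — so the pattern-recovery studies use an
experiment-A-like design (two conditions, three time points).

## Functional profiles

RPKM = count / (length/1000) / (mapped total/1e6).  Genus activity is
the per-sample share of classified reads, with genera never reaching 1%
pooled as "Other taxonomic assignments".  Pathway fractions are reads on
pathway-member genes over reads on all annotated genes (annotated =
carries ≥ 1 EC or KO); the default member set is the starch-and-sucrose /
glycoside-hydrolase-13 enzymes (EC 3.2.1.1, 3.2.1.10, 3.2.1.11,
3.2.1.20, 3.2.1.33, 3.2.1.68, 3.2.1.135, 2.4.1.1, 2.4.1.25).  Partial
ECs such as "3.2.1.-" match no specific member unless prefix matching is
enabled.  Per-organism per-enzyme tables sum member-gene RPKM per
(genus, EC) over a sample subset (24/48 h by default).

EC recovery from free-text domain names normalizes both sides: lowercase,
punctuation to spaces, drop the generic tokens {type, terminal, subunit,
domain, enzyme, like} and stray single-letter alphabetic fragments
(digits are kept — they carry substrate positions), collapse whitespace;
exact normalized equality yields the EC, with a multiplicity flag when a
gene matches more than one.  The enzyme-name dictionary is an input
table; a small synthetic fixture ships with the tests.

Activity-vs-16S agreement is Spearman correlation (average-rank ties)
per genus over matched samples, plus a pooled estimate over all
(genus, sample) pairs.

## Cross-project comparison

Bray–Curtis dissimilarity BC = 1 − Σ min(p, q) on relative abundances
(profiles are aligned on the taxon union and renormalized with a warning
if needed).  "Inversion" is 1 − BC; ordination runs PCA on the rows of
the similarity matrix, matching pipelines that feed a similarity matrix
row-wise into a generic PCA; classical PCoA on BC is offered as an
alternative mode.  BC is a semimetric (no triangle inequality) and PCA
scores are defined only up to rotation/sign, so tests compare distances,
never raw coordinates.  A consequence of the row-PCA construction is
that duplicating every sample scales embedded distances by √2 (the
feature dimension doubles); the shape is preserved.

## Synthetic data

The generator emulates the study design: five conditions (blank control
plus IMMP-27/94/96/dig27), time points 0/6/12/24/48 h, two replicates,
with experiment A/B membership assigned by condition.  Defaults: 8
genera × 40 genes, negative-binomial counts with dispersion α = 0.3
(variance μ + αμ²), expected depth 1e5 reads per sample with log-normal
library sizes (σ = 0.3), and a Poisson contamination of 0.1 expected
counts in exactly-zero cells so zero handling is exercised.

Gene means factor into base weight × genus trajectory × pattern profile.
Genus trajectories implement four planted co-occurrence clusters
(t0 peak, IMMP-responsive rise, steady, control-only late); gene patterns
are planted in proportions 15% t0-only, 10% control-late, 45% up-late,
30% flat.  Planted trajectories are defined on this pre-depth surface;
per-sample depth rescaling can locally distort monotonicity of the
realized means, which is intended (it is what normalization must undo).
Hit tables contain true-lineage hits engineered to pass every filter and
three decoy classes each engineered to fail exactly one (bit-score ≤ 50,
length ≤ 100, below the 10% band), with the designed post-filter LCA
recorded as truth.  16S tables are produced by a Gaussian-copula rank
coupling that re-orders each genus's own activity values, giving exact
rank identity at ρ = 1 and approximate Spearman ρ otherwise (Pearson
parameter 2·sin(πρ/6)).

What the synthetic data does not emulate: real taxonomies' uneven depth
and polyphyly, database misannotation, multi-mapping reads, compositional
coupling between genera beyond the planted trajectories, and batch
effects between experiments A and B.  Passing tests therefore demonstrate
algorithmic correctness and calibration under the stated noise model, not
performance on real libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script use desk-scale problems chosen
to make the statistical checks sharp: 30-leaf taxonomies with exhaustive
≤ 4-leaf subsets for the LCA oracle; 2000-gene, 2-condition × 2-time ×
2-replicate benchmarks (10 seeds) for null calibration; 12-row planted
profile matrices over 20 seeds for stability recovery; 3 × 40 genes for
pattern recovery; 500 samples for correlation recovery.  Two-sided
discrete p-values use a 1 + 1e-7 slack on the observed pmf when summing
outcomes, the standard guard against ties lost to floating point.  The
dispersion estimate is clipped to [0, 10].  k-means sub-seeds are drawn
from one generator so a single seed reproduces every partition; DBSCAN
labels are order-dependent only for border points, which the planted
fixtures avoid by construction.
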
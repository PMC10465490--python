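# Methods

This note documents the models and procedures implemented in `barcodewga`,
their assumptions, the parameters that matter, and the design choices made
where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Barcode design and error correction

Barcodes are fixed-length DNA words selected greedily in lexicographic
order (A<C<G<T) from all 4^L candidates, keeping a word iff it passes the
composition filters and sits at Hamming distance ≥ d from every previously
kept word. Defaults: L=6, d=3, homopolymer runs ≤ 3, GC fraction within
[0.10, 0.90] inclusive (for 6-mers this means 1–5 G/C bases; words with GC
strictly above 90% or below 10% are excluded). A minimum distance d
guarantees unique correction of up to ⌊(d−1)/2⌋ substitutions, so the
default design tolerates one sequencing error in the barcode. Greedy
lexicographic order was fixed for determinism; other traversal orders give
different (similarly sized) codes, so only the yield's scale (≥ 48 under
the defaults; the implementation returns 110) and the distance guarantee
are meaningful, not the specific words.

## Demultiplexing

The barcode occupies the first L bases of read 2. A prefix is assigned to
the unique barcode within `max_mismatch` (default 1); with d=3 and radius 1
a read within one substitution of its true barcode can never be captured by
another barcode, so misassignment requires ≥ 2 errors in L=6 bases
(~10⁻⁵ at a 10⁻³ per-base error rate). `N` counts as a mismatch to every
base. Ties (possible only when the caller relaxes the radius beyond
⌊(d−1)/2⌋) are reported as AMBIGUOUS, never broken silently.

**Swap model.** In a two-group mixing experiment (groups A and B of
barcodes amplifying different species), a uniformly swapping read picks any
of the other barcodes as destination. With |A|=47 and |B|=1 and uniform
per-barcode read depth, the observed rate of A-origin reads under B
barcodes is |A|/|B| = 47 times the converse — the asymmetry is a property
of the group sizes, not of the chemistry. `estimate_swap_ratio` reports
both observed rates and this expected ratio; groups with zero assigned
reads are flagged rather than divided by.

## Barcode-bias model and rebalancing

Observed per-barcode read counts are modeled as
count_i ∝ efficiency_i × concentration_i, with efficiency a stable,
barcode-sequence-specific multiplier (the generator draws it lognormal with
CV 0.30, matching the spread seen in pooled barcoded-MDA libraries before
correction). Under this model one rebalancing cycle
c_i′ ∝ c_i · mean(obs)/obs_i inverts the bias exactly; with multiplicative
lognormal measurement noise σ the CV converges to roughly the noise floor
instead, and the trajectory is non-increasing in expectation. Both
properties are asserted by simulation; the number of cycles (real
experiments used 3) and the noise floor are configuration, because the real
efficiency vector is unknowable. Rebalancing conserves the barcoded-primer
subtotal and the total hexamer concentration exactly, and clips
concentrations at 1% of the mean so no barcode is locked out. The CV is
population SD / mean (the sample-SD convention would differ by
√(n/(n−1)) ≈ 1% at n=48; a choice had to be fixed and documented).

**Barcoded depth estimator.** `estimate_barcoded_depth` converts amplified
mass to molecule count at the amplicon length and multiplies by barcoded
fraction and captured fragment length over genome length. It is a
parameterized calculator — linear in every argument — because the mapping
from amplification fold to usable depth depends on capture details that
vary per protocol; no specific output value is asserted.

## Copy-number analysis

*Variable bins.* Genome windows (default 2 kb) carry a mappability weight;
bins are built per chromosome by cutting the cumulative weight at equal
quantiles, so each bin carries the genome-wide target weight to within one
window's weight and bins never cross chromosomes.

*GC normalization.* A robust LOWESS fit (fraction 0.3, 3 robustifying
iterations) of count on GC estimates the expected count at each bin's GC;
ratios count/fit are rescaled to mean exactly 2. The near-diploid
assumption matters: a genome with a large aberrant fraction f at copy c
is compressed by 2/(2+f(c−2)); state calling is therefore relative, as in
all mean-normalized read-depth methods.

*CBS.* Recursive circular binary segmentation: within each interval the
arc maximizing |mean(arc) − mean(rest)| / (σ√(1/k+1/(n−k))) is found over
all arcs leaving every resulting segment ≥ `min_width` (default 5) bins;
σ is the MAD of successive differences /√2, robust to the change points
themselves. Significance is hybrid: a permutation p-value when
α ≥ 1/(nperm+1), otherwise (e.g. at the default α=10⁻¹⁰, unreachable by
1000 permutations) a Bonferroni-style Gaussian tail bound over the arcs
tested. After recursion, adjacent segments whose means differ by less than
`undo_sd`·σ (default 0.8) are re-merged. On pure noise the bound is
conservative, so spurious splits are rare (asserted: ≥ 99/100 shuffled
vectors yield one segment); on a 2→4 step at σ=0.2 the argmax localizes
the breakpoint within ±2 bins (asserted over 50 replicates).

*MergeLevels.* Segment levels with the closest means are compared by a
two-sample Wilcoxon rank-sum test on their bin values and pooled while
p > 0.1. The rank-sum test approximates the Ansari–Bradley step of the
original MergeLevels procedure at the same threshold; both are rank tests
of distributional difference, and the location contrast is what matters
here.

*States and export.* Levels within ±0.3 of 2 are neutral, below loss,
above gain (the threshold is configuration; published pipelines leave it
implicit). Heatmap export is log2(ratio/2). Concordance against a bulk
profile: sensitivity = exact state match on bulk-aberrant bins,
specificity = neutral on bulk-neutral bins.

*Lorenz/AUC.* Bins sorted ascending by count; curve = cumulative read
fraction vs cumulative bin fraction; AUC by trapezoid. Uniform counts give
0.5 exactly; for lognormal(σ) counts the AUC approaches (1−G)/2 with
G = 2Φ(σ/√2) − 1, used as a closed-form oracle.

## Consensus SNV calling and quality estimators

A site is confident iff ≥ `min_callers` (2) distinct callers support it in
each of ≥ `min_samples` (2) samples. The two-sample requirement suppresses
amplification artifacts because independent per-sample false positives
coincide with probability FPR^2 ≈ 10⁻¹⁰ at FPR 10⁻⁵. Per sample, a
confident site is called if any caller reported it, or if the Fisher
rescue fires: one-sided Fisher exact on
[[n_alt, n_errmax], [depth−n_alt, depth−n_errmax]], where n_errmax is the
*largest* count among the two other non-reference bases — the most
conservative contrast against the sequencing-error background — at
p < 10⁻³, uncorrected (the threshold is fixed, not a family-wise level).
Base counts are assumed pre-filtered to MQ > 30 and BQ > 30 reads. The
rescue requires ≥ 1 read by default (`min_rescue_depth`); sites that are
neither called nor rescued are `low_coverage` below 5 reads, else
`not_called`.

*ADO.* At bulk-confirmed heterozygous SNPs with single-cell depth ≥ 10, a
dropout is exactly one allele with zero reads; the rate is events over
assessed sites. The generator implements an ADO event as "with probability
`ado`, exactly one randomly chosen allele is lost", so the measured rate is
an unbiased estimate of the parameter (if instead each allele dropped
independently with probability q, the measured rate among covered sites
would be 2q/(1+q), not q — the event-level definition matches how dropout
is scored).

*FPR.* Confident homozygous sites are bulk positions with depth ≥ 20 and
exactly one observed allele; the FPR is somatic calls at those sites over
sites interrogated. At truth 10⁻⁵ over 10⁶ sites only ~10 events are
expected, so recovery checks average 5 replicates to keep the Poisson
counting error well inside the factor-2 band.

## Phylogeny and spatial statistics

The variant matrix codes 1 = detected (at any depth), NA = not detected
with coverage < 5, 0 = not detected with adequate coverage. Pairwise
distances are Manhattan over jointly non-NA sites, rescaled by
n_sites/n_used; the rescaling can break the triangle inequality, which is
accepted (the tree method consumes dissimilarities, not metrics). A pair
with no jointly assessable site is an error, not a silent zero.

The tree is built by neighbor joining — the greedy heuristic for balanced
minimum evolution — followed by nearest-neighbour interchanges accepted
while Pauplin's balanced length Σ 2^(1−p_ij) D_ij decreases. Branch
lengths are OLS on the final topology, negatives clamped to zero and
flagged. An artificial all-zero, fully-assessed diploid taxon is appended
before distance computation and the output Newick is rooted there, giving
every tree an ancestral reference point.

PCA imputes NA to 0 (unassessable treated as reference — consistent with
how the binary profile is used elsewhere), centers columns, and fixes each
component's sign by its largest-magnitude loading. Moran's I uses
row-standardized k-nearest-neighbour weights (k=4 default; inverse-distance
available): I = (n/W) Σ w_ij z_i z_j / Σ z_i², zero diagonal. For
row-standardized weights I is bounded by [−1, 1] and its permutation-null
mean is −1/(n−1), both asserted.

Subclone consolidation: an SNV or kataegis mutation is present in a
subclone iff detected in a strict majority of its microniches (an exact
half is conservatively absent; configurable); an SV is present iff
detected in ≥ 2 of the subclone's samples or in bulk.

## SV tiers and kataegis

SV calls cluster by single linkage when type, strand orientation and
chromosome pair match and both breakpoints are within 1 kb (the common
merging default); representatives are per-end medians, translocations are
stored chrom1 < chrom2. Tier *high* keeps multi-sample (≥ 2) clusters
built from the trusted per-sample subset (somatic calls of the second
caller plus high-confidence calls of the third); tier *bulk_supported*
keeps all-caller clusters present in bulk AND in ≥ 2 samples — the
conjunctive reading matches the tier's name and the downstream use of bulk
as confirmation; a disjunctive mode is available. Clusters with either
breakpoint in a low-mapping-quality region are removed in both tiers.

Kataegis input SNVs must be detected in ≥ 6 samples with > 20 total
supporting reads (strict); events are maximal runs of ≥ 6 mutations with
successive inter-mutation distances ≤ 1 kb — the field-standard rainfall
criterion. At a background density of 1 mutation / 100 kb the chance of a
spurious run is < 0.05 per 10 Mb replicate (asserted against a brute-force
window oracle).

## Synthetic data: what it emulates, and what it does not

The generator is the package's instrument for testing every stage against
known truth. Defaults (all configurable on `SimConfig`):

| parameter | default | role |
|---|---|---|
| genome | 2 chromosomes × 10 Mb, 2 kb windows | small enough for a < 3 s end-to-end run |
| clone structure | 4 subclones × 3 microniches, binary genealogy | truncal 100, clade 30, subclone 50, within-subclone 15, per-sample 10 SNVs |
| barcode efficiency CV | 0.30 | pre-correction bias regime |
| MDA overdispersion σ | 0.3 | lognormal per-bin multiplier |
| ADO | 0.15 | event-level, see above |
| per-base error | 10⁻⁵ | pileup error scatter |
| caller sensitivities | 0.80 / 0.85 / 0.90 | three pseudo-callers, FPR 10⁻⁵ each |
| CNA depth | 10⁶ reads | copy-number track |
| spatial layout | 2×2 contiguous subclone patches | positive Moran's I regime |

The clonal genealogy is deliberately a fixed *binary* tree (within each
subclone one sample pair shares an extra edge), so "Robinson–Foulds 0 to
truth" is well defined; real tumors have no such resolved truth. Bin
counts are Poisson around weight × (copy/2) × GC-bias × lognormal noise.
Barcoded reads carry the barcode (with substitutions) plus a random
suffix; only the barcode region is sequence-realistic.

Passing tests on this generator demonstrates that the *algorithms* recover
the parameters and structures they are designed for under the stated noise
regimes. It does not demonstrate performance on real data: real MDA noise
is spatially autocorrelated along the genome, real callers make correlated
errors, real mappability tracks are far rougher than the uniform weights
simulated, and real tumors are aneuploid enough to strain the mean-2
scaling.

## Problem sizes and numerical choices

Simulation-backed checks use: 100 replicates × 2000 sites (ADO), 5 × 10⁶
sites (FPR), 50 × 1000 bins (CBS), 50 × (10 samples × 500 variants)
(consensus), 50 × 12 taxa (phylogeny), 100 × 100 positions (kataegis
null) — sized so the default suite completes in about a minute on one
core while keeping binomial/Poisson error well inside each asserted band.
`scripts/acceptance.py` re-runs the same analyses at moderate replicate
counts (30/5/25/10/20) from a single `--seed`. All randomness flows
through `numpy.random.default_rng`; dataset generation is a pure function
of (config, seed), and set iteration never feeds the RNG (ordering is
sorted first), so outputs are identical across processes and platforms.

Known limitations: CBS's analytic p-value is a Bonferroni bound (slightly
conservative; very short low-amplitude segments near α may be missed);
NNI search is first-improvement hill climbing, adequate at microniche
scale (tens of taxa) but not guaranteed globally optimal; the Fisher
rescue ignores strand information; indels and multi-allelic records are
out of scope throughout.
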
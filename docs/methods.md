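# Methods

This note records the models, parameter choices and numerical conventions
behind `radnet`, and what the synthetic-data generators do and do not
establish.

## Discovery pipeline

**Demultiplexing.** A read pair is assigned to a line iff read 1 starts with
the line's 5 nt barcode immediately followed by the SacI remnant and read 2
starts with the same barcode followed by the MseI remnant, both exactly
(0 mismatches).  Exactness is a design constraint, not an optimization:
barcodes sit next to a fixed remnant, so error correction would trade a
known-clean assignment rule for cross-line contamination.  Quality strings
are carried but unused; no quality filter is applied by default because the
appropriate upstream filter is platform-specific.

**Trimming.** Each mate loses its 5 nt barcode and the error-enriched last
5 nt, leaving 80 nt that include the restriction remnant.  Reads too short
to survive are counted and skipped, never truncated.

**Tags and networks.** Tags are exact (r1, r2) sequence pairs with per-line
counts.  The singleton filter requires ≥ 2 total reads *and* presence in
≥ 2 lines — both conditions target sequencing-error derivatives, which are
overwhelmingly line-private singletons.  Networks are connected components
under per-end Hamming distance ≤ 2 (ungapped: restriction tags are
fixed-length, so indel variants are invisible by construction).  The
implementation one-hot encodes sequences and uses a matrix product for
all-pairs distances; it is checked in the test suite against a brute-force
union-find oracle.

**Error tolerance rate.**  On an edge (A, B) with total_count(A) ≤
total_count(B), A is an error derivative of B when
count_A/(count_A + count_B) ≤ ETR.  The ETR statistic is evaluated on
panel-total counts with default 0.03.  Removal proceeds in *simultaneous
sweeps*: every tag flagged by any current edge is removed, edges are
recomputed among survivors, and the sweep repeats to a fixed point.  A
sequential edge-at-a-time rule would be order-dependent in count chains
(removing the middle tag first can rescue the smallest); the sweep semantics
are deterministic and permutation-invariant, which the suite tests
explicitly.  Equal counts give ratio 0.5, above any admissible ETR
(valid range [0, 0.5)), so ties remove nothing.  Components are re-derived
after removal because pruning can disconnect a network, and only networks of
2–10 tags proceed to allelic calling.

## Relative-heterozygosity discrimination

Presence of a tag in a line means count ≥ `min_depth` (default 1; raise it
on deep panels to suppress contamination-driven false heterozygotes).  For
each unordered tag pair the panel is tabulated into n_het / n_hom_a /
n_hom_b; lines carrying neither tag are ignored and lines carrying a third
network tag are counted at face value by their pairwise pattern — excluding
them would bias H_R for tags embedded in large homeolog families.

H_R = n_het / min(n_hom_a, n_hom_b); when the smaller homozygote class is
empty the pair is uninformative and H_R is +inf (never allelic).  The
acceptance threshold is *strictly* below 0.20.  Within a network, candidate
pairs below threshold are accepted greedily in ascending H_R (ties: larger
homozygote support, then lexicographic sequence order), each tag consumable
once.  Multiple disjoint pairs per network are allowed deliberately — a
network mixing two homeologous loci contains two legitimate allelic pairs —
and how overlapping candidates should be reconciled is genuinely open; the
greedy-disjoint rule is a simple, deterministic resolution.  Every
mismatching position of an accepted pair becomes a SNP; the representative
SNP is the lowest-offset one (arbitrary but fixed — the SNPs of one tag pair
are in complete LD, so the choice carries no information).

## LD statistics

Inbred genotypes are haploidized (het → missing) rather than phased: with
essentially homozygous lines, an EM phase step would only add noise.
r² is the squared Pearson correlation of 0/1 indicators over
pairwise-complete lines, identical to D²/(p(1−p)q(1−q)); estimates from
fewer than 10 informative lines are treated as undefined (configurable).
The background LD uses the nearest-rank (ceiling) percentile — stated
explicitly because percentile conventions differ — over anchor pairs on
*different chromosomes* only.  Map assignment copies the best anchor's
chromosome and cM verbatim (no interpolation; the data contain no
information about which side of the anchor the marker sits on).  Ties on
max r² break by more informative lines, then lowest (chromosome, cM).

LD pruning slides a 50-marker window in steps of 5 (step exposed); within a
window the highest-r² offending pair loses its lower-MAF member (tie: the
later map position), and the retained set is audited against its own
post-condition in the tests.

## LD decay

The fitted form is the Hill–Weir drift expectation of r² at C = ρ·d with the
sample-size term n fixed at the panel size; only ρ is free (fitted on a log
scale by Levenberg–Marquardt least squares).  Distances are not binned.
The decay distance solves E(r²)(d) = background by bracketed root-finding on
the fitted monotone curve; when the background exceeds the curve's ceiling
E(r²)(0) the result is explicitly "no crossing" rather than an extrapolated
number.

## Haplotype blocks

D′ confidence intervals come from a likelihood over |D′| ∈ {0, 0.01, …, 1}:
observed two-locus haplotype counts (haploid lines counted directly) are
scored under haplotype probabilities moved from equilibrium toward the
maximal D of the observed sign, and the 90% interval trims 5% of normalized
likelihood mass from each tail.  Pairs are strong LD when CI ∈
[≥ 0.70, ≥ 0.98] and strong recombination when the upper bound is < 0.90;
other pairs are uninformative.  A candidate interval is a block when its
bounding pair is strong LD and ≥ 95% of its informative pairs are strong LD
(the bounding-pair condition follows the standard CI-model practice and
prevents two-marker chance candidates); intervals are restricted to a 10 Mb
window, resolved longest-span-first without overlap, and discarded below
100 kb.  Pair tallies for all O(m²) candidate intervals use 2-D prefix sums.

Group classification: a block with no ≥ 1 bp overlap in the other group and
≥ 50 kb long is group-specific (the specific-block length floor is 50 kb
while the panel-wide filter stays at 100 kb); overlapping blocks are common;
a common pair is preferential when the *pooled-major* haplotype on the
shared SNPs differs in frequency between groups by > 0.40.  Which haplotype
defines "frequency difference" is an open convention; the pooled-major
choice is symmetric under group exchange, which the suite verifies.
`classify_blocks` takes the two group panels as arguments because the
per-group block objects alone cannot supply pooled haplotype frequencies.

## Trait arithmetic

PIC = 1 − (p² + q²) − 2p²q² (clamped at 0 against floating-point
cancellation near fixation).  Broad-sense heritability
H² = σg²/(σg² + σge²/n + σe²/(nr)) over n environments and r replicates.
The genome-wide significance threshold is 1/n_markers.  Haplotype-phenotype
summaries drop lines with any missing call in the block, suppress
haplotypes below 2 lines, and compare the major haplotype against the
pooled rest with a Welch t-test.

## Synthetic data: what it emulates and what it does not

The read-panel generator's defaults are the reference scenario used by the
validation suite: 96 fully inbred lines split 72/28 into two groups
(Balding–Nichols divergence, F = 0.15), 500 biallelic loci whose alleles are
tag pairs differing at 1–3 positions placed outside the restriction
remnants, 100 homeolog families of 2–4 mutually similar tags co-present in
*every* line (the hardest case for H_R — constitutive heterozygosity, rather
than a segregating homeolog), Poisson(8) depth per present tag, and 0.2%
per-base substitution errors.  No indels, no PCR duplicates, no realistic
quality scores, no read-depth overdispersion: a green pipeline test
establishes that the discrimination logic is correct under the stated error
model, not that any particular wet-lab library will behave identically.

Pipeline recall is measured against *discoverable* loci — both alleles
carried by ≥ 2 lines in the truth genotypes — because a locus fixed in the
sampled panel is undiscoverable by any reference-free method, and the
singleton filter excludes single-line alleles by design.

The genotype-level generator draws haplotypes from a Gaussian copula:
adjacent markers share a latent correlation sin(π/2·√E(r²)) (the inverse of
the tetrachoric reduction, so realized binary r² tracks the drift
expectation at the configured ρ), and ancestral frequencies follow a slow
logit random walk along each chromosome, since markers in strong LD share
genealogy and therefore similar frequencies.  Distant-pair correlation
decays as the product over adjacent pairs — faster than the drift curve —
so the generator is a realistic LD *texture*, not a coalescent.  Planted
features (perfect-LD blocks, group-specific blocks, phenotype effects with
chosen variance components) are recorded in truth tables, and all tests
score against those truth tables rather than against distributional
assumptions.

## Known limitations

* Genotypes are presence/absence-based; read-depth dosage and hemi-SNP
  rescue are out of scope.
* Error-tag removal assumes errors derive from a high-count neighbour
  within the same network; systematic errors shared across lines can
  survive (they are then usually rejected by H_R instead).
* The LD-decay form is one published drift expectation; other decay
  parameterizations would need a different expectation function but can
  reuse the fitting/crossing machinery.
* Physical positions are consumed from a map table; sequence alignment to a
  reference genome is deliberately not performed.
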
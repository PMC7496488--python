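# Methods

## The read-count CNV model

Exome capture yields, per sample *k* and capture target *j*, a fragment
count `x_jk` proportional to library size `s_k`, target capture efficiency
`e_j`, target length, and the local copy ratio. Because capture efficiency
is a property of the probe, it cancels between a test sample and a
reference built from other panel members: under diploidy the proportion
`x_j / (x_j + r_j)` is approximately constant across targets, where `r_j`
aggregates the chosen reference samples. This is the classical
optimized-reference design for exome CNV detection, re-implemented here
from its ingredients rather than wrapped.

**Reference selection.** Candidates are ranked by Pearson correlation of
their normalized count profiles with the test sample and aggregated
greedily while a power proxy increases: the expected beta-binomial
log-likelihood ratio for a copy-ratio-0.5 event evaluated at the expected
deleted count, with the overdispersion re-estimated per candidate set by
method of moments. Adding samples grows the trial counts (power up) but
heterogeneous samples inflate overdispersion (power down); the greedy stop
balances the two. Capped at 10 reference samples; fully deterministic.

**Emission model.** `x_j ~ BetaBin(n_j, p_j(c), φ)` with `n_j = x_j + r_j`,
`p_j(c) = c·μ / (c·μ + (1−μ))`, copy ratios `c = 0.5 / 1 / 1.5`, and `μ`
the add-one-smoothed ratio of summed test counts to summed trials
(constant across targets because efficiency cancels). `φ` is the
intra-class correlation (`a = p(1−φ)/φ`, `b = (1−p)(1−φ)/φ`); at `φ = 0`
the binomial log-pmf is returned exactly. `φ` is estimated per sample by
bounded 1-D maximum likelihood after trimming the 2% most extreme
standardized residuals per tail, so a sample's own CNVs do not inflate its
diploid dispersion estimate.

**HMM.** Three states (DEL, DIP, DUP). From DIP the probability of
entering either CNV state at the next target is `t = 1e-4`; inside a CNV
state the self-transition is `(1 − 2t)·exp(−d/L)` with `d` the genomic gap
between consecutive targets and `L = 1000` bp the expected CNV extent, so
exons of one gene are glued into single events while distant targets must
re-pay the entry cost. Viterbi decoding per chromosome; maximal non-DIP
runs become calls with confidence `Σ_j [ll(state) − ll(DIP)]`. Targets with
`n_j = 0` contribute no evidence. Because the model compares a sample
against references, it reports categorical relative states, not integer
copy numbers; the `0.5/1/1.5` ratios encode heterozygous single-copy loss
and gain, the smallest detectable changes.

**Known limitation (mirror calls).** At a high-frequency deletion the
reference aggregate of a non-carrier is itself depleted, so the
non-carrier scores as relatively duplicated (and vice versa). These mirror
calls are real relative copy differences but carry the opposite label;
they are intrinsic to every reference-based read-ratio caller, concentrate
at common sites, and cap per-carrier event recall (≈ 0.5–0.65 under the
default carrier spectrum) while leaving site-level recovery ≥ 0.9. The
recovery benchmark therefore scores at the CNV-site level — the unit of
the panel analysis: recall requires a same-type detected site over a truth
site (≥ 3 carriers, ≥ 3 coverage-surviving targets); precision requires a
detected site to fall on a truth copy-variable locus of either type.
Event-level recall is reported alongside as a supplementary quantity.

## Panel summaries

Same-type calls overlapping by ≥ 1 bp are linked (single linkage; touching
intervals do not link) into CNV sites; a call survives the rarity filter
iff its site has ≥ 3 distinct carriers. Densities are counts per Mb of
merged captured sequence; the totals row recomputes from summed counts
over summed lengths. Chromosome rate pairs are compared with the exact
conditional Poisson test (condition on the summed count; two-sided
"minlike" binomial tail, delegated to `scipy.stats.binomtest`), optionally
Holm-adjusted across the 21 pairs — entries of exactly 1 in adjusted
tables are the cap. Group densities are means of per-sample densities with
percentile-bootstrap intervals (1,000 resamples over samples); no named
between-group test is attached because none is defined for this contrast.

## Phylogeny

Genotypes are binary presence/absence per typed site (DEL and DUP sites
remain distinct columns, so no three-level coding is needed). Euclidean
distance on binary rows is `sqrt(Hamming)`. Neighbor joining follows
Saitou–Nei: join the pair minimizing
`Q(i,j) = (n−2)d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)`, limb lengths
`l_i = d(i,j)/2 + (r_i − r_j)/(2(n−2))`, ties broken at the lowest
(row, col) index, negative limb estimates clamped to zero with a warning.
On additive matrices the reconstruction is exact (topology and lengths to
1e-9), which the tests verify against randomly generated trees and an
exhaustive least-squares topology search at n = 5. Output is an unrooted
tree (trifurcating root) serialized as Newick via scikit-bio.

## SD detection

Annotated repeats are hard-masked with N so no alignment seed can start in
them; the masked genome is split into 250-kb chunks and each chunk is
aligned back to the whole. The aligner indexes exact 31-mers (N-free),
samples query seeds every 4 bp, groups matches by (target chromosome,
diagonal), folds diagonals within 100 bp together, splits chains at seed
gaps > 2 kb, extends each chain ungapped with match +1 / mismatch −2 and
X-drop 30, and computes percent identity from the edlib global edit
distance over the extended pair: `100·(1 − dist/max(len_q, len_s))`, the
matches-over-columns convention. Filters: alignment ≥ 1 kb, identity
≥ 95%, self-hits removed (same chromosome, diagonal within 100 bp, > 50%
reciprocal overlap — stricter than exact-coordinate equality to absorb
end jitter), A→B/B→A duplicates canonicalized. Both sides of surviving
hits are merged into disjoint SD regions; hit-level counts are kept
because the identity-threshold ladder counts alignments, not regions, and
the two can disagree. Alignments spanning chunk boundaries may be split at
the boundary (documented limitation; with 250-kb chunks and ≤ 10-kb SDs
this affects ~4% of pairs at worst). A blast `-outfmt 6` ingestion path
(1-based inclusive, minus-strand subject coordinates normalized) feeds the
same filter/merge stages for genomes beyond the internal aligner's scale;
a test cross-checks the two routes with real `blastn`.

## Association statistics

`randomize_intervals` keeps each feature's chromosome and length and draws
its new start uniformly over all positions where it fits entirely inside
one non-masked interval (slot-weighted across intervals); features may
overlap after placement. The permutation test randomizes the *feature* set
(the smaller elements — SDs fit the inter-repeat gaps; CNV sites spanning
whole genes generally do not) against the fixed second set,
`p = (1 + #{null ≥ obs}) / (n_perm + 1)` for overlap enrichment ("less"
for closest-distance), z-score against the null moments, and both the
null mean and null extremes are reported since an "expected bound" can
mean either. Binned densities use the midpoint rule (each feature counted
once; bin counts sum to the feature count); the Spearman profile pools
bins across chromosomes at each size of the ladder
{40, 80, 160, 320, 640, 1000, 1500, 2000} kb and flags sizes with
p < 0.001 (tie-corrected rank correlation, t-approximation, via scipy).

## GO enrichment

The ontology arrives as two TSVs (gene→term, child→parent); annotations
are propagated to ancestors before testing (true-path rule). Per-term
over-representation is the hypergeometric upper tail. The elim pass walks
terms leaves-first; a term with current-set p below `alpha_elim = 0.01`
has its annotated genes removed from all ancestors before they are tested,
which dissolves enrichment that is purely inherited. BH q-values are
emitted for both the raw and the elim column — the raw column is the
conventional one to threshold, since elim p-values are not exchangeable —
and the differential contrast takes as study set the genes overlapped by
CNV sites whose carriers are exclusively wild accessions.

## The synthetic-data generator

The generator emulates the study system at desk scale. Genomes: 2 × 2 Mb
by default, GC 0.44, interspersed repeats from a 12-motif library filling
25% of each chromosome, SD pairs (1–10 kb, identity 95–99% realized by
substituting exactly `round((1−identity)·L)` positions of the copied donor,
so the planted identity is exact), placement of SDs biased toward
chromosome-arm ends (density `1 + 4·(2|x−L/2|/L)²`, mirroring the terminal
SD enrichment of real chromosomes), and 400 genes of 4–8 exons (150–500 bp,
near the 359-bp average of the real capture design) placed independently
of SDs with an optional forced-overlap fraction. Panels: samples split
wild/landrace/cultivar (6/45/49%), library factors lognormal(0, 0.2),
capture efficiencies lognormal(0, 0.5) with a 15% poorly-captured
subpopulation at 5% efficiency — this produces the below-5× target tail
that the coverage filter removes, matching a design in which ~80% of
targets exceed 5×. Expected counts are
`λ_jk = s_k·e_j·(len_j + footprint)·c_jk / Z`: fragments overlapping a
target include those centred in one 200-bp footprint of flank, which is
what fragment-overlap counting does and what reproduces realistic
fragments-per-target yields (~100–150 at 40×); `Z` normalizes the panel
mean depth to 40×. Counts are Gamma–Poisson with dispersion 0.01 — a
deliberate mild mismatch with the caller's beta-binomial so that recovery
results are not an artifact of fitting the generating model. CNV sites
occupy 3–8 consecutive targets, deletions with probability 0.79
(emulating the ~3.8:1 deletion:duplication ratio), carrier frequencies
Beta(0.4, 4) (rare-dominated with an upper tail above 40%), wild samples
carry deletions at 1.5× the panel frequency, and site placement is
weighted `1 + β·(SD bp in a 100-kb window)/window` with `β` the single
association knob (0 = independent placement). For phylogeny scenarios a
`group_private_fraction` of sites is carried only within one group
(within-group frequency Beta(3, 1.5)), giving the group-specific CNV
repertoires that population structure produces.

What the generator does **not** emulate: mapping bias and mappability,
GC-dependent coverage curves, reference-genome errors, linkage between
sites, and SD-mediated mis-mapping (in real data SDs corrupt read mapping
*and* promote CNVs; here only the placement association exists). Passing
recovery tests therefore demonstrates correctness of the statistical
machinery under a faithful noise model, not robustness to alignment
artifacts.

## Problem sizes and numerical choices

The shipped benchmarks use: 100 samples × ~2,350 targets (150 planted
sites) for caller recovery; 50 SD pairs in 2 Mb for SD recovery; a 4 × 8 Mb
genome, 500 sites, β = 100 for the association profile; 200 null
replicates × 200 permutations for type-I calibration; 200–500 random
instances for the Viterbi and NJ exactness checks. Empirical p-values use
the add-one rule and are never zero; the exact Poisson test is
conservative at small counts (discreteness), so only the upper bound of
the type-I confidence interval is binding. Overdispersion optimization is
bounded in [1e-8, 0.5] with `xatol = 1e-7`; a boundary solution is
returned with a warning. All randomness flows from explicit integer seeds
through `numpy.random.default_rng`; fixing the seed fixes every output
byte of the generator.
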
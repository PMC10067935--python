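# Methods

This note documents the models and procedures `snp2path` implements, the
choices made where the design was genuinely open, and what the synthetic
world does and does not establish.

## SNP functional categories and ancestry comparison

Each SNP carries exactly one controlled-vocabulary consequence term; the
vocabulary maps terms to categories and categories to super-groups
(non-coding, regulatory, coding, ncRNA). SNPs with multiple consequence
terms are rejected rather than silently resolved — conflicts surface as
errors. ncRNA (lncRNA + miRNA) is tracked as its own super-group because the
ancestry contrast concentrates there, and it can also be folded into
non-coding totals when summarizing.

Between-ancestry category proportions use the pooled two-proportion z-test,
two-tailed, without continuity correction. Flags are raw p < 0.05 per
category with **no** multiplicity adjustment — that is the published
decision rule being reproduced — but Benjamini–Hochberg adjusted p-values
are emitted alongside for transparency. Degenerate contract: when the pooled
proportion is 0 or 1 the statistic is defined as z = 0, p = 1. Shared
(both-ancestry) SNPs appear once per ancestry in long format, so they count
in both denominators.

## The E/T/C/P evidence cascade

eQTL, regulatory-element and coding lookups are independent: one SNP may
yield E, T and C assignments simultaneously, and all target genes of a hit
are emitted (targets are unioned across sources; no per-tissue
deduplication beyond exact duplicates). Only SNPs with no E/T/C hit receive
a proximal (P) assignment, so P-exclusivity holds at the SNP level while
gene-level class sets may still overlap. All genes are treated as equal
entities regardless of evidence class.

Coordinates are 1-based, fully closed. The chr6 exclusion window
(28,014,374–33,683,352) is applied with closed endpoints before any mapping.
Proximal distance is 0 inside a gene interval, otherwise the smaller gap to
either interval end; ties break lexicographically by gene symbol. Both
conventions are arbitrary where the published procedure is silent; they are
fixed here for testability.

The differential-expression ingestion filter keeps probes with FDR strictly
below the threshold (default 0.2) and then the single most significant probe
(smallest p, ties by probe label) per gene. Normalization and the moderated
test that produce such tables are deliberately out of scope — they belong to
the upstream microarray pipeline.

## Category over-representation

Enrichment of a query set against a category is the one-sided
(over-representation) exact hypergeometric tail P(X ≥ a) on the 2×2 table
over the annotation library's own universe (not the genome): both functional
and cell-type schemes define their own coverage. The odds ratio is the
sample OR = ad/bc, with OR = ∞ when bc = 0 and ad > 0, and OR = 0 when
ad = 0. The published flag rule is OR > 1 **and** −log p > 1.33; the log is
read in base 10 (threshold p < 10^−1.33 ≈ 0.0468, consistent with the p <
0.05 convention used throughout), since a natural log would place the
threshold at p ≈ 0.264. The sidedness of the original test is unstated; the
one-sided choice matches a rule that only ever reports enrichment, never
depletion. BH-adjusted p-values are emitted but do not feed the flag.
Ranked summaries order enriched categories by p ascending with ties broken
by label.

## PPI networks, the connectivity gate, and MCODE

Subnetworks are induced on a STRING-dialect edge list after a confidence
cutoff (default 400, STRING's "medium"; the source analysis does not state
one). Duplicate/reciprocal rows collapse to the highest score; self-loops
drop.

The connectivity gate approximates the (unpublished) STRING enrichment null
with a degree-product (Chung–Lu) model: λ = Σ_{u<v} min(1, k_u·k_v/2m) over
query-node pairs with degrees and edge count from the background network,
and p is the upper Poisson tail of the observed edge count; the gate passes
iff p < 10⁻¹⁶ strictly. Caveat: because the null conditions on the
background's realized degrees, a query that *is* most of the background —
or whose dense modules are part of the background, as in the reference
synthetic world — yields an unremarkable p. The gate is decisive for small
queries against a large background (a planted 10-clique in a sparse
500-node graph passes by many orders of magnitude), which is the regime the
published rule addresses. The pipeline records the gate outcome rather than
silently halting.

MCODE is implemented from its canonical definition: vertex weight = k ×
density of the highest k-core of the vertex's closed neighborhood (weight 0
below the degree cutoff); complexes grow breadth-first from the
highest-weight unassigned seed, admitting neighbors with weight ≥
(1 − node_score_cutoff) × seed weight, never reusing vertices already in a
complex; complexes lacking a 2-core are dropped and a single haircut pass
removes singly-connected members (the seed is retained so every surviving
cluster contains its seed). Parameters are the plugin defaults (degree
cutoff 2, node score cutoff 0.2, k-core 2, max depth 100, haircut on, fluff
off). All tie-breaks (seeding, BFS order, cluster ranking) are
lexicographic for determinism. Cluster score is seed weight × size.

Two behavioral consequences of the seed-relative growth rule are worth
stating plainly, because they bound what cluster-recovery benchmarks can
show: (i) two equally dense modules joined by even one edge between
high-weight vertices merge into a single complex; (ii) in a module of
density ~0.8–0.9, members whose local weight falls below 80% of the module
maximum are excluded and later re-seed small fragments. Real protein
networks escape (i) because module boundaries pass through low-weight
nodes; synthetic block models do not, which drove a generator design choice
(below).

Metastructures report per-cluster size, intra-cluster edges and
inter-cluster edges, with the conservation identity Σintra + Σinter +
(edges touching unclustered nodes) = |E| asserted on every call. The
random-gene null draws an equal-size uniform cohort from the network's
nodes and compares cluster size / intra / inter distributions with Welch's
t-test (95% CIs reported; two zero-variance samples fall back to an exact
equality test). The curated "overall function" grouping of clusters is data,
not code: a configurable category→group map (immune, tissue repair,
metabolic, motility, cell stress, general) with a deterministic round-robin
default for synthetic schemes.

## Single-sample signature scores and downstream statistics

For expression matrix x (genes × samples, log2 scale) the scorer estimates a
per-gene CDF at each observed value. Gaussian kernel (default):
ẑ_ij = (1/n) Σ_k Φ((x_ij − x_ik)/h_i) with h_i = s_i/4 (sample SD, floored
at 10⁻⁸ for constant genes); alternatively a pure rank/ECDF kernel. Within
each sample genes are ranked by ẑ descending (ties lexicographic by gene
label) and the symmetric rank statistic r = |p/2 − rank|^τ (τ = 1) weights a
KS-like random walk: in-set steps add r normalized by the set's total,
out-of-set steps subtract 1/(p − m). The default summary is the magnitude
difference — largest positive walk deviation plus largest negative
deviation — bounded in [−1, 1]; maximum-absolute-deviation is available as
an option. A set covering every matrix gene has no out-of-set steps and
scores 0 (flagged degenerate); sets with fewer than min_set mapped genes are
skipped with a warning; a sample whose ẑ are all tied (e.g. a constant
matrix) scores 0 by the tie contract.

Invariance properties, precisely: the ECDF kernel makes scores exactly
invariant to any strictly increasing per-gene transformation; the Gaussian
kernel is exactly invariant only to increasing *affine* maps, because a
nonlinear monotone map can reorder kernel-CDF values across genes within a
sample. Reversing a sample's complete ranking flips the score's sign only up
to O(1/p), because r is off-by-one asymmetric under rank reversal; the test
asserts sign flip plus magnitude agreement at that order.

Group comparisons use Welch's unequal-variance t-test with Satterthwaite
degrees of freedom (two zero-variance groups: exact mean equality, t = 0 and
p = 1 when equal). Score–covariate relationships use simple OLS with
R² = squared Pearson correlation and a two-tailed t-test on the slope;
constant x is an error, constant y returns slope 0, R² = 0, p = 1.
Panel reports support subgroup filters expressed as metadata queries (e.g.
`SLEDAI >= 6` for active patients) and report the n actually used.

## The synthetic world

The generator states one fixed world; its defaults are the analysis's
published counts where those exist and a single a-priori choice where they
do not:

- **SNPs**: 757 EA / 700 AsA with 20 shared; positions uniform over 22
  synthetic chromosomes of 120 Mb with ~2% of SNPs deliberately inside the
  chr6 exclusion window so the filter is exercised; association p-values
  log-uniform in [10⁻⁸, 10⁻³]. Category proportions per ancestry mirror the
  published distribution: ~70% non-coding and 8% coding in both cohorts,
  AsA ncRNA (11%) ≈ 2× EA (6%), EA regulatory (16%) > AsA (11%). Shared
  SNPs draw consequences from the two ancestries' averaged proportions.
- **Lookups**: per-SNP hit rates 0.45 (eQTL; between the published 29% EA
  and ~60% AsA), 0.07 (regulatory; 105/1437) and 0.03 (coding; 44/1457);
  genes per hit are 1 + Poisson with means 3/6/1 respectively, mirroring
  the published targets-per-SNP ratios (1955/631, 964/105, 47/44). The
  targets-per-SNP distribution is a config knob because the real lookup
  tables' distribution is unpublished.
- **Gene universe**: 5000 deterministic tokens (G000001…) on non-overlapping
  20 kb intervals, ~227 per chromosome. Annotation: 54 exclusive functional
  categories; 30 overlapping cell categories on ~40% of genes. Planted
  enrichment draws "signal" gene sets with in-category odds multiplied
  (default category FC001, odds 5).
- **PPI**: 400-node background at noise edge probability 0.05 (mean degree
  ~20, a medium-confidence-network scale) with 5 planted modules of 12 at
  within-probability 0.8, drawn from the lookup-linked genes so the planted
  complexes sit inside the SNP-predicted cohort. Planted edges score
  700–999, noise edges 150–999. **Deliberate departure from a textbook
  stochastic block model**: no noise edges are drawn between two distinct
  planted modules. Planted modules are ground-truth complexes whose
  separability downstream recovery must be able to measure, and the
  seed-relative MCODE growth rule merges equally dense modules across any
  high-weight bridge; keeping module–module pairs edge-free makes
  "recoverable planted structure" a property of the world rather than an
  accident of noise. Module–background and background–background noise
  edges are unaffected.
- **Expression**: 1000 genes × (20 cases + 20 controls), baselines uniform
  in [4, 12] log2 units, i.i.d. Gaussian noise (SD 1). Heavier-tailed noise
  is a non-goal; the kernel-CDF machinery is exercised without it. Each
  planted set's latent activity is a_s = δ·1[case] + N(0, 0.25), applied
  coherently to the set's genes within a sample (δ = 1.0 for the default
  planted 25-gene set; 10 decoy sets of 25 carry no shift). Metadata are
  linear in the chosen signature's activity: SLEDAI-like 6 + 4a (clipped at
  0), anti-dsDNA-like 50 + 30a, C3-like 100 − 20a (the complement variable
  couples negatively, as observed clinically), each plus Gaussian noise.

Everything is generated from `numpy.random.default_rng` streams derived from
one seed; outputs are byte-reproducible and referentially closed (every
emitted identifier belongs to the declared universe or SNP table).

What a green synthetic test does *not* establish: realism of linkage
structure (no LD, allele frequencies or genotypes — the pipeline consumes
post-association lists), realistic PPI degree heterogeneity (Bernoulli
blocks, not scale-free), microarray artifacts (no batch effects, no probe
structure), or clinical validity of the metadata couplings. The world
verifies bookkeeping, statistical contracts and parameter recovery, not
biology.

## Numerical and degenerate-input conventions

- Exact hypergeometric tails via scipy's `hypergeom.sf`, verified against
  rational-arithmetic enumeration to 10⁻¹² in tests.
- p-values floored at the smallest positive double before taking −log₁₀.
- Poisson tail p-values may underflow to exactly 0 below ~10⁻³⁰⁰; the
  gate's strict `< 1e-16` comparison is unaffected.
- Welch/OLS implemented in closed form with explicit degenerate contracts
  (above) rather than NaN propagation; independent scipy/statsmodels
  routines serve as test oracles only.
- Empty inputs: empty SNP table is legal for generation and categorization
  but aborts the pipeline at the mapping stage with the stage named; empty
  graphs cluster to an empty list; empty effective enrichment queries and
  empty gene lists for category fractions are errors.

## Known limitations

- The MCODE benchmarks at the stated desk scales expose the algorithm's
  seed-relative exclusion behavior: ~0.9-dense planted modules are recovered
  only up to 1–3 low-weight members, and cluster-count comparisons against
  sparse random cohorts have single-digit degrees of freedom. Two acceptance
  checks encode stricter expectations than canonical MCODE can meet at those
  scales and are intentionally left failing rather than loosened; the
  corresponding unit-level properties (exact clique recovery, weight
  oracles, disjointness, determinism) are green.
- The connectivity gate's degree-product null is an approximation to
  STRING's internal model and is conservative when the query dominates the
  background (see above).
- The scorer's Gaussian-kernel invariance is affine-only by construction;
  use `kcdf="ecdf"` when full monotone invariance matters.
- Cluster→overall-group assignment is a label map supplied as data; the
  published grouping was curator judgment and is not reproduced, only made
  configurable.
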
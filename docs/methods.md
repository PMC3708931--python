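# Methods

## Pipeline overview

`coexmod` chains four stages: genome integration (copy-number
recurrence plus curated gene lists → hub gene set), MI network
inference around the hubs, overlapping module detection, and a
reproducibility manifest. Each stage is usable on its own; the driver
(`coexmod.pipeline.run_pipeline`) wires them together under a single
seed.

## Genome integration

For each platform, the recurrence of a (locus, state) pair is the
fraction of *distinct* assayed samples carrying at least one gain
(resp. loss) call overlapping the locus; call-free samples count in the
denominator. Thresholds are inclusive (`frequency >= min_fraction`),
per platform — 0.15 is the conventional choice for SNP-array cohorts
and 0.40 for small CGH cell-line panels — and a sample carrying both a
gain and a loss call at a locus contributes to both rows (the non-lossy
choice; such samples are rare under the generator, which never emits
both states for one sample-locus).

Cross-platform intersection is state-stratified and operates on bp
intervals (0-based, half-open throughout): the retained region is the
*intersection* of the overlapping parent loci, not either parent, so a
narrow SNP-array peak nested in a broad CGH band survives as the peak.
Genes are mapped by any-overlap between their annotated locus and a
retained region. The merged gene list (CNV ∪ mutation ∪ GWAS, with
per-symbol provenance) is finally restricted to genes with ≥1
expression probe and a GO term; hub *probes* (the union over member
genes) seed the network, since probes, not symbols, are network nodes.

## MI estimation

Two estimators, both returning nats:

* **binned** — plug-in MI on equal-frequency bins (ordinal ranks,
  `floor(sqrt(n))` bins unless set); constant vectors yield 0 by
  definition. The contingency-table MI itself is delegated to
  scikit-learn's `mutual_info_score`.
* **kernel** (default, the "accurate" mode) — a Gaussian-kernel density
  plug-in on copula-transformed data. Because MI is invariant under
  strictly monotone marginal transforms, the estimator works on
  *normal scores* (ranks/(n+1) mapped through the standard normal
  quantile) rather than directly on the rank-uniform scale: the
  rank-uniform scale has hard [0, 1] boundaries where kernel density
  estimates are strongly biased, and that bias propagates into MI
  (measured error up to 0.13 nats at ρ = 0.9, n = 1000 for a plain
  rank-scale plug-in — outside any useful band). Two further standard
  corrections are applied:
  * leave-one-out densities, which cancel the self-kernel term exactly
    (a plain plug-in is biased upward by ≈ K(0)/(n f̂) under
    independence);
  * Richardson extrapolation over bandwidths (h, √2·h): the leading
    smoothing bias of a KDE plug-in is O(h²), so 2·Î(h) − Î(√2 h)
    removes it; conveniently the √2-wide kernel matrix is the
    elementwise square root of the base one, so both evaluations share
    one matrix.

  The auto bandwidth is the Silverman rule h = 1.06 n^(−1/5) (the
  normal-scores marginals have unit variance by construction);
  `kernel_width` overrides it. Estimates are clamped at 0. Measured
  accuracy on the bivariate-normal closed form −½ ln(1−ρ²) at n = 1000
  over 100 seeds: max |error| 0.003 (ρ = 0), 0.062 (ρ = 0.5), 0.074
  (ρ = 0.9).

Network construction batches the hub-versus-all MI computation: kernel
matrices are precomputed per probe and combined per sample index with
BLAS matrix products, which makes the 100-hub × 2000-gene × 150-sample
reference scenario run in seconds while remaining arithmetically
identical to the pairwise estimator.

## Threshold calibration

The MI threshold for a requested P-value p is calibrated from a
permutation null: `null_permutations` random gene pairs with one
profile's samples shuffled, estimated with the same estimator. The
upper decile of the empirical survival curve is fitted with an
exponential tail, ln P(Î > t) ≈ α − β t, and the threshold is
t* = (α − ln p)/β — this extrapolates to Bonferroni-scale P-values
(e.g. 5·10⁻⁶) far beyond the reach of the permutation count. A
`calibration="quantile"` fallback returns the empirical (1−p) quantile
for small runs. p = 1 maps to threshold 0; fewer than 100 permutations
is a calibration error. At p = 0.05 the fitted threshold falls inside
the 94th–96th percentile band of its own null (verified in the tests).

## Network construction and DPI

With a non-empty hub set, candidate edges are exactly the pairs with at
least one hub endpoint ("subnetwork around the seed list" semantics);
an empty hub set means all pairs. An edge is kept iff
Î ≥ max(threshold, mi_floor); `mi_floor` defaults to 0. DPI pruning
then marks, in every triangle, the edge with the *strictly* smallest
MI when it is below (1 − ε)·min(other two); all marks are computed
against the pre-pruning network and applied at once, so the result is
independent of triangle visitation order, and exact ties remove
nothing. ε defaults to 0. Components are reported largest-first (ties
by smallest node label), and components containing no hub probe are
removed.

## Module detection

Two detectors over the same `DetectionParams`:

* **k-core complex prediction** (unweighted topology). weight(v) =
  k · density(K) where K is the highest non-empty k-core of v's
  *closed* neighborhood (closed keeps isolated-node weight at 0, k = 0).
  Growth seeds from the highest-weight unassigned node and BFS-adds
  unassigned neighbors with weight ≥ (1 − vwp)·weight(seed); vwp
  defaults to 0.2. The growth phase is non-overlapping by
  construction. Post-processing drops complexes without a non-empty
  2-core, optionally fluffs (absorb outside neighbors with
  edges-to-complex / |complex| above the fluff threshold — the only
  overlap source on this path) and optionally haircuts (trim to the
  2-core).
* **cohesiveness growth** (MI-weighted). From each seed (default: every
  node not yet covered, in descending weighted-degree order), greedily
  add the boundary node or remove the member that most increases
  f(C) = W_in / (W_in + W_bound + penalty·|C|), stopping at a local
  maximum (every emitted module certifies that no single-member
  removal increases f). Modules below `min_module_size` (default 3) or
  `density_floor` (default 0) are discarded; pairs with overlap score
  ω ≥ 0.8 are merged to a fixpoint. The penalty defaults to 0.

Subcluster removal drops module A iff some strictly larger B contains
at least `containment_threshold` (default 1.0, i.e. strict subset) of
A's members, judged against the original set in a single pass — no
cascade, and equal sizes never trigger removal. `merge_most_similar`
returns the union of the pair sharing the most members (ties: larger
ω, then lexicographic ids). Module statistics report the module count,
the gene count with multiplicity (Σ|C|), and the unique gene count,
collapsing probes to genes through the annotation when given.

The pipeline's default detector is the cohesive one: on MI networks the
k-core path ignores edge weights, and after DPI pruning planted
clique-like modules become sparse, nearly triangle-free graphs on which
the unweighted k-core weighting degenerates (leaf vertices outweigh
internal ones), so the weighted objective is the robust default.

## Synthetic data

The generator emulates the study inputs at configurable scale:

* **expression** — a latent-factor model: gene g in module m has
  profile Σ_m a_m f_m + ε with f_m ~ N(0,1) per sample and
  ε ~ N(0, σ²); overlapping memberships sum their loadings; background
  genes are pure noise. Two genes sharing one module have correlation
  a²/(a² + σ²). Defaults for planted-recovery work: 5 disjoint modules
  × 20 genes, a = 1, σ = 0.5 (within-module ρ = 0.8), 200 samples, all
  module members hubs — under the hub-restricted candidate rule a
  module with only a few hub members induces a star, which no
  density-based detector can score, so the planted "disease genes" are
  the hub set itself.
* **segment calls** — per sample × locus, one uniform draw yields gain
  with probability p_g, loss with p_l, otherwise no call (never both
  states). Platforms have independent streams keyed by (seed,
  platform), so adding a platform never perturbs another.
* **gene lists** — mutation/GWAS lists of exact sizes with an exact
  overlap count (the 141/41/overlap-1 configuration reproduces the
  181-unique-gene union).
* **annotation** — genes laid on synthetic chromosomes in 10 kb steps
  (or placed explicitly), with tunable fractions lacking probes or GO
  terms; listed genes can be protected as always-eligible.

The reference end-to-end scenario (`synthetic_default`) uses 2000 genes
× 150 samples, ten modules of 20; the first five sit on loci recurring
at rate 0.3 on a 216-sample SNP-array cohort and 0.6 on two 9-sample
CGH panels (all above their 0.15/0.40 thresholds), next to decoy loci
that recur below threshold or on one platform only; mutation/GWAS lists
are drawn from the hub-module genes. These sizes keep a full
double-run (for byte-reproducibility checking) under a couple of
minutes on one CPU while preserving every qualitative feature of the
full-scale analysis.

What the generator does **not** emulate: probe-level noise structure of
real arrays (multiple probes per gene, saturation, batch effects),
LOH/allele-specific copy number, correlated gain/loss segments along a
chromosome, and non-Gaussian expression marginals. Passing recovery
tests therefore demonstrates correctness of the algorithms under the
factor model, not performance guarantees on real microarray data.

## Determinism

All randomness flows from one integer seed through named substreams
(CRC32-keyed `numpy` `SeedSequence`s) per stage/platform. Float
accumulations that feed serialised output iterate in sorted order, and
writers emit canonical node/edge order with shortest-round-trip float
repr, so identical configurations reproduce byte-identical outputs
across processes (verified in the acceptance suite).

## Known limitations

* The exponential tail fit assumes an exponentially decaying null MI
  tail; heavy-tailed nulls (tiny sample counts) would bias t*. The
  empirical-quantile fallback covers p-values within the permutation
  budget.
* Cohesive growth is greedy; it certifies local, not global, maxima,
  and on DPI-pruned sparse graphs it can fragment one true module into
  several (the subcluster-removal and merge steps mitigate, not
  eliminate, this).
* `remove_subclusters` at thresholds < 1 judges near-containment
  against the original set only; iterating to a fixpoint would remove
  more.
* Interval operations are O(calls × loci) — adequate for recurrence
  analyses at cytoband-scale locus counts, not for megabase-scale
  segment catalogues.
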
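# Methods

## Model and assumptions

`pcnet` treats pathway crosstalk as a two-layer inference problem.  The
gene layer is a correlation graph: for the focal group's n samples, the
Pearson correlation of every gene pair is tested with the exact t
transform (two-sided, n−2 df), which is the correct null distribution when
expression values are approximately Gaussian on the log scale.
Benjamini–Hochberg runs over the family of *all* distinct gene pairs after
filtering — not only nominally significant ones — which is the standard
family definition and makes the q-values independent of any later
thresholding.  The |r| ≥ 0.5 magnitude threshold and the q < α criterion
are applied conjunctively, so their order is irrelevant.

The pathway layer assumes that crosstalk between two pathways is carried
by the correlated gene pairs that straddle them.  A gene belonging to k
pathways contributes each of its edges to every distinct pathway pair it
can form (deduplicated within the edge), reflecting that multi-membership
genes (common in curated annotations) genuinely couple many pathways.
Self-pairs (P = P) are excluded: the object of interest is *between*-
pathway communication.  The edge weight is the arithmetic mean of
contributing correlations, so a pathway edge carried by 36 coherent gene
edges and one carried by a single chance edge can have the same weight —
the contributing count (`n_gene_edges`) and the redundancy metrics exist
precisely to separate those cases.

Significance is assessed by label permutation rather than analytically,
because the pathway-edge weight is a mean over a *data-dependent* edge
set.  Pooling the focal and matched background samples and relabeling m
pseudo-focal samples per replicate re-runs the entire pipeline, so every
selection step (FDR, |r| threshold, aggregation) is inside the null.
Replicates in which a pathway pair forms no edge score weight 0 — keeping
replicate vectors conformable and penalizing rarely-formed edges, which is
conservative.  The add-one estimator p = (1 + #{|w_null| ≥ |w_obs|})/(R+1)
cannot return 0 at finite R; with R = 150 the attainable floor is
1/151 ≈ 0.0066.  Comparisons use |w| because negative crosstalk is as real
as positive.  All retention thresholds are strict (`p < α`, `q < α`), so a
p-value of exactly 0.05 is dropped.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha_gcn` | 0.05 | FDR level for gene edges |
| `r_threshold` | 0.5 | optional magnitude floor on gene-edge \|r\| (set null/0 to disable) |
| `alpha_pcn` | 0.05 | retention level for permutation p-values |
| `permutations` | 150 | null replicates R; p-floor is 1/(R+1) |
| `abs_percentile`, `var_percentile` | 0.10 | low-signal gene filters (fraction of genes cut) |
| `filter_combine` | union | combine the two filter criteria by union or intersection |
| `normalize` | true | apply quantile normalization before filtering |
| `hub_k` | 10 | hub-list length used in reports |
| `seed` | 0 | master seed; replicate r uses the sub-stream (seed, r) |

All probabilities are dimensionless; expression values are log-scale
intensities (unitless).  The "absolute expression" filter summarizes a
gene by the mean of |value| across samples; the across-sample variance
filter is applied after normalization so it is scale-free; both cuts are
strict-below with the inclusive linear-interpolation quantile, so a gene
sitting exactly on the boundary is kept.

## Quantile normalization dialects

Two tie conventions are provided.  `ties="average"` (default, the common
array-pipeline dialect) gives tied values the mean of the reference values
at their tied ranks; with ties present, columns then match the reference
distribution only up to tie-averaging, and the transform is idempotent
only up to the same collapsing.  `ties="rank"` breaks ties by stable input
order and assigns reference values directly by rank; every column's sorted
vector is then *exactly* the reference and the transform is exactly
idempotent, ties included.  The two dialects coincide on tie-free data.
When the input columns already share one sorted vector, that vector is
used as the reference directly (averaging bit-identical columns would
perturb the fixed point by one ulp).

## The synthetic generator

`pcnet.synthetic` draws both groups from zero-mean multivariate normals:
correlation `rho_within` inside each pathway's gene block, `rho_cross`
between planted pathway pairs (focal group only when `focal_only`), and
independence elsewhere; positive definiteness is verified by Cholesky
factorization at build time (a planted block at ρ_c across blocks of g
genes with within-correlation ρ_w requires 1 + (g−1)ρ_w > g·ρ_c).
Adjacent pathways share `overlap_fraction` of their genes — membership
overlap only, the covariance is untouched — to exercise the
multi-membership aggregation rule.  Categories are assigned round-robin
from a configurable label list so category-circle grouping always has
material to work on.

What the generator does *not* emulate: microarray noise physics
(background, saturation, probe effects), heavy-tailed expression,
gene-specific baseline intensities, and batch structure.  Consequently the
generator's output is best read as *already normalized* data; pipeline
runs on synthetic panels set `normalize: false`, because quantile
normalization applied to a panel of only tens of genes is a coarse rank
discretization that measurably attenuates planted correlations (r 0.7 →
≈0.45 on a 24-gene panel).  On real data with thousands of genes the
transform is near-monotone per sample and this effect is negligible.
Passing tests on synthetic data therefore demonstrate the correctness of
the inferential machinery under the stated generative model, not
robustness to array artefacts.

## Study designs used by the tests and the acceptance script

- *Calibration* (no signal): three independent 20-pathway × 8-gene
  datasets, 50 + 50 samples from one distribution, R = 150, pooling 570
  pathway pairs.  The gene-edge FDR gate is held open (α > 1, no |r|
  floor) for this study: under a global null a gated network is almost
  empty, pathway weights collapse onto an atom at zero and their p-values
  onto 1, so the uniformity of p-values — the property being measured —
  is only visible on the continuous ungated weight statistic.  With the
  gate open, observed and null pipelines are exchangeable by construction
  and the fraction of edges at p < 0.05 is expected at 7/151 ≈ 4.6%.
- *Recovery* (planted signal): 6 pathways × 8 genes, focal-only cross
  block at ρ_cross = 0.8 between two non-adjacent pathways,
  ρ_within = 0.8 (the positive-definiteness bound above forces
  ρ_within ≥ 0.77 at this block size), `overlap_fraction` 0, 50 samples
  per group, default pipeline parameters, 50 (tests) or 20 (acceptance
  script) replicates.  Overlap is disabled here because a pathway sharing
  a gene with a planted block carries genuine focal-only signal through
  that gene, which would blur the planted/unplanted scoring; overlap is
  exercised by the aggregation oracle and the end-to-end pipeline runs
  instead.
- *End-to-end*: a 10-pathway dataset with two planted blocks, a random
  4-drug target map, R = 150, full artifact set.  Sizes throughout were
  chosen so each study completes in seconds to a few minutes on one CPU
  while leaving Monte-Carlo margins wide relative to the asserted bands.

## Numerical and design choices

- Ranks and hub lists break ties lexicographically on node id; giant
  components break size ties by smallest member — all outputs are fully
  deterministic.
- Edge lists store each unordered pair once (lexicographically smaller
  node first), rows sorted, floats at 6 decimals; reading back reproduces
  the edge set bit-for-bit at that precision.
- 4-node circles are counted inclusively (chords permitted) as simple
  cycles up to rotation and reflection, via common-neighbor pairs over
  node pairs with canonical-form deduplication.
- Gene-deletion p-values re-run the *stored* permutation label
  assignments on the reduced gene set, so before/after p-values share one
  Monte-Carlo draw and differences are attributable to the deletion
  alone.  Correlations among surviving genes are not re-estimated:
  deleting a node does not change the remaining data.
- `hub_expectation` is a deliberate heuristic (no closed form exists for
  "how connected should this pathway be"): pathways are ranked by summed
  member-gene GCN degree and by member-gene count, the two ranks are
  averaged and re-ranked, and the discrepancy observed_rank −
  expected_rank is reported (positive = less connected than the naive
  prediction).  It is isolated in a single function and reported as a
  diagnostic, never used by other stages.
- Drug target sets are resolved against the network at use time; unknown
  pathways are logged and ignored, and sets sharing targets are treated
  as having identical effect.
- The per-pathway-pair permutation test is two-sided on |weight|; feature
  significance additionally reports one-sided tails, with the two-sided
  value as twice the smaller tail (capped at 1).

## Known limitations

- Pearson-only edges: rank-based or mutual-information relationships are
  out of scope in this version.
- Permutation cost scales linearly in R and in the all-pairs correlation;
  very large gene panels (≫10⁴ genes) would need a blocked or thresholded
  correlation pass that is not implemented.
- Empirical p-values are bounded below by 1/(R+1); with R = 150 no edge
  can be reported below 0.0066, and multiplicity across pathway pairs is
  not re-adjusted at the pathway layer (the permutation null is already
  pipeline-wide, but a per-edge 0.05 level still implies some false
  positives among thousands of pairs).
- Deletion is binary node removal; partial knockdown, dose, and synergy
  are not modeled.
- Betweenness/bottleneck centrality is intentionally absent from the
  feature bundle.
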
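# Methods

Precise definitions of the statistics implemented in `mirpath`, the
parameter defaults, and the scope and limitations of each stage.

## Gene set enrichment (`mirpath.gsea`)

**Ranking.** Genes are ranked by signal-to-noise
`(μ_D − μ_C) / (σ_D + σ_C)` with each class sd floored at `0.2·|μ|` of its
class mean (a Student t-statistic is available via `metric="t_stat"`).
Ties, including the degenerate all-zero case, break lexicographically by
gene id, so rankings are always deterministic.

**Enrichment score.** For a pathway S over a ranked list of N genes, the
running sum increments by `|r_i|^p / Σ_{hits}|r_j|^p` at members (weight
`p = 1.0` by default) and decrements by `1/(N − |S|)` at non-members. ES is
the signed extremum of the walk; on a magnitude tie (exact, or within the
float precision of the cumulative sums) the positive deviation is
preferred. If all member weights are zero the hit increments fall back to
`1/|S|`.

**Leading edge.** Members at or before the peak for ES > 0, at or after
the peak for ES < 0; empty for ES = 0.

**Null and NES.** The null permutes phenotype labels when both classes
have ≥ 7 samples, otherwise it falls back to gene-set permutation
(logged). `NES = ES / mean(|null ES of the same sign|)`; the empirical
p-value is the fraction of same-sign null ES with `|ES_null| ≥ |ES|`.
Pathways are called differentially expressed at Benjamini–Hochberg
FDR < 0.01 over the empirical p-values. Size filter: 10–500 mapped genes
by default (`gsea_min_size`/`gsea_max_size`).

## Differential expression (`mirpath.diffexp`)

Two-sample Student t-test (equal variance) per feature; BH step-up FDR.
Degenerate zero-variance features: equal class means give `t = 0, p = 1`;
unequal means give `p = 0` (logged).

## Targeting profiles (`mirpath.profiles`)

`c[pathway, miR]` counts the pathway's leading-edge genes the miR targets
(interaction edges require ≥ 2 evidence sources, enforced at load time).
Pathways with empty leading edges are excluded; miRs targeting no
leading-edge gene are dropped; the remaining columns are Z-normalized
across pathways (ddof = 1), dropping constant columns.

## Forest local importance (`mirpath.importance`)

Each of `n_trees = 10,000` regression trees (CART, `mtry = ⌈√m⌉` features
per split) is grown on a without-replacement subsample of ⌊2/3·n⌋
pathways. The local importance of miR j for pathway i is the mean, over
trees where i is out-of-bag, of the increase in that tree's squared
prediction error for i when feature j is permuted among the out-of-bag
cases (only features actually used by a tree are evaluated; unused
features contribute zero exactly).

**Null calibration.** `n_null = 100` replicates permute the NES vector and
each miR column independently across pathways and recompute the full
importance matrix with replicate-specific seeds, giving per-pair null mean
μ and sd σ. The observed importance is tested one-sided:
`Z = (L − μ)/σ`, `p = Φ̄(Z)`, with BH correction jointly across all pairs
and `FDR < 0.01` defining significant pairs. Pairs with σ = 0 cannot be
calibrated and are excluded (logged, counted). An IM is a miR with ≥ 1
significant pathway; an OIM is an IM in every analyzed condition.

**Known property.** The observed forest can exploit whichever feature is
best correlated with the response by chance, while the per-pair
column-permutation null cannot; the calibration is therefore mildly
anticonservative. Measured over 20 no-signal cohorts (40 pathways × 60
miRs, 1,000 trees, 50 null replicates), the mean fraction of pairs called
at nominal FDR < 0.01 is ≈ 0.017 — above the nominal rate but within a
factor of two. This is intrinsic to the calibration design, not a seed- or
scale-dependent artifact.

## Correlation change (`mirpath.corr_change`)

For an interaction edge, Pearson correlations are computed per class and
compared as `ΔZ = (atanh r_D − atanh r_C) / √(1/(N_D−3) + 1/(N_C−3))`,
requiring ≥ 4 samples per class; correlations of ±1 are clamped just
inside the open interval when `clamp=True` (the pipeline default).
Positive ΔZ is a gain of correlation in disease, negative a loss;
`|ΔZ| > 1.0` marks the reported gain/loss edges. The pipeline restricts
edges to those linking a significant pair's miR to the pathway's
leading-edge genes.

## Downstream statistics (`mirpath.downstream`)

- **Enrichment curves.** For each k, the group is the set of IMs with ≥ k
  significant pathways; `E(k)` is the observed overlap with an annotation
  list divided by the mean overlap over 10,000 uniform redraws of the
  label set from the candidate universe. Curves truncate at the first
  empty group.
- **Overlap tests.** Upper-tail hypergeometric p for set overlaps;
  two-sided Fisher exact p for 2×2 tables (scipy implementations, tested
  against exhaustive enumeration).
- **Overlap summaries.** OIM/pathway/pair intersections with percentages
  `100·|∩|/|set|` rounded half-up to one decimal (documented convention;
  `round_half_up`).
- **Clustering.** Ward linkage on Euclidean distances over the rows and,
  independently, the columns of a binary association matrix; deterministic
  scipy leaf order; cluster labels by `maxclust` cut.

## Synthetic cohorts (`mirpath.synthetic`)

Gaussian log-scale expression (baseline means U(4, 10), noise sd 1.0).
Planted structure, all recorded in `SyntheticTruth`:

- a fraction (default 0.1) of pathways is dysregulated: member genes
  shifted by ±δ (default 2.0) in the disease class, alternating direction;
- planted important miRs (default 5) preferentially target (80% of their
  30 edges) shifted genes of a single direction each;
- a subset of each planted miR's shifted targets (default 4) is coupled to
  the miR within one class only — disease for "gain" edges, control for
  "loss" — via `gene = class mean + β·(miR − miR mean) + noise` with
  β = ±3.0 (`corr_strength`, sign by the `repression` flag);
- cohort size 20+20 by default; all identifiers drawn from fixed id
  spaces so independently generated cohorts share a candidate universe.

Limitations: expression is Gaussian and uncorrelated apart from the
planted couplings; pathway overlap means dysregulation bleeds into
non-planted pathways that share shifted genes (visible as extra
enrichments in examples); no batch effects, no count noise, no
miR-mediated causal simulation.

## Determinism and seeds

All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning (cohort generation, GSEA
permutations, per-tree subsamples and sklearn tree seeds, null
replicates). `RunConfig.stage_seed(stage)` derives per-stage seeds from
the master seed by SHA-256, and every output table carries a 16-hex-digit
hash of the full configuration. Repeated runs are byte-identical.
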
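# Methods

## Scope and model

`dctopo` compares the gene–gene correlation structure of two sample
groups A and B over a common gene set. The data model is a complete
(no missing values) genes × samples matrix of log2 expression values
per condition, with equal group sizes `n_A = n_B = n`. Equal sizes are
enforced by default: with unequal groups the two correlation estimates
have different sampling variability, which masquerades as differential
correlation. An `allow_unequal` override exists for exploration and
warns.

All topology is computed on the Fisher-transformed correlation matrix
`z_ij = atanh(c_ij)`. The transform stabilizes the variance of the
correlation estimate (SD ≈ `1/sqrt(n − 3)`), so an equidistant
threshold series on the z scale probes weak and strong correlations
with comparable resolution, and interval lengths on that scale can be
referred to a normal distribution (Steiger's test).

## Threshold grids

A grid is the series `t_m = m · z_max / k`, `m = 1..k`. Conventions:

- Zero is excluded. A threshold of 0 connects every positively
  correlated pair — a near-complete graph carrying no information —
  and "the grid covers `(0, z_max]`" keeps both the count `k` and the
  equidistance exact.
- `z_max` defaults to the largest off-diagonal `|z|` over both
  condition matrices, so the grid spans the full range of correlations
  present in the data; it can be overridden (e.g. fixed to 2.5, i.e.
  Pearson ≈ 0.985, for cross-dataset comparability).
- Defaults `k = 200` for DCglob and `k = 100` for DCloc. The two
  algorithms keep independent grids; the finer DCglob grid sharpens
  the resolution of run lengths, which directly become p-values.
- Edges use the *signed* correlation (`z_ij > t`): negative
  correlations never create edges by default. An
  `absolute_correlation` option thresholds `|z|` instead.
- "Exceeds" is strict (`>`, not `≥`).

Within one subsampling/FDR analysis the grid is resolved **once** (from
the observed pair when not supplied) and shared by the observed run and
every null run: detection counts at a cutoff are only comparable when
all score vectors were computed over the same threshold series.

## DCglob

At each threshold, connected components with ≥ 3 genes are extracted
from both networks (with < 3 nodes there is no topology to compare;
pairwise changes are better tested directly). Genes clustered in both
conditions are removed; components are then *recomputed* on the
induced subnetworks, and genes in ≥ 3-components of exactly one
induced network are exclusive to that condition. This
remove-then-recompute rule is conservative: a component that only
survives through genes shared with the other condition does not count.

Sweeping the grid yields boolean indicator profiles `I^A_j, I^B_j`.
Conventions adopted where the procedure leaves freedom:

- The run interval `[a, b]` spans the grid values of the first and
  last indicator of the longest run, so a single-point run has length
  0 and maps to p = 0.5 (one-sided, Z = 0).
- Genes never exclusive at any threshold receive p = 1, ranking
  *below* an observed zero-length run: "no evidence" is weaker than
  "evidence of length zero".
- The p-value is one-sided (run lengths are nonnegative by
  construction); the two-group comparison uses the independent-samples
  standard error `sqrt(1/(n_A − 3) + 1/(n_B − 3))`.
- Tie between the best A-run and best B-run of equal length: the run
  with the higher mean threshold (stronger correlations) wins, then A.
  For a single gene, nonempty ties cannot actually arise from data:
  membership in a ≥ 3-component is monotone in `t` (components only
  shrink), so the A-eligible and B-eligible threshold ranges are
  nested rather than interleaved, and one profile is always empty.
  The tie-break exists for robustness and for hand-constructed
  profiles; ties *between genes* (mirror-symmetric data) are real and
  are resolved by stable sorting on gene id.

## DCloc

Per threshold and gene, `d_i^t = 1 − |V_A ∩ V_B| / |V_A ∪ V_B|` over
the open neighborhoods (the gene itself excluded; including it would
add one shared member and bias `d` downward), zeroed when
`|V_A ∪ V_B| < 3`. The score is the grid average `d_i ∈ [0, 1]`.

The per-gene direction is not part of the core definition; the package
reports `signed_sum = Σ_t d_i^t · sign(|V_A| − |V_B|)` and assigns the
direction from its sign — the condition in which the gene is better
connected, weighted by how much the networks disagree. The output
table also carries the mean neighborhood sizes per condition, which
make the direction auditable.

## FDR estimation

Null model: draw two *disjoint* groups of sizes `n_A, n_B` uniformly
without replacement from the pooled cohort, ignoring labels
(overlapping groups would share samples and understate null DC). Run
the chosen algorithm on each of `B = 100` such pairs (default), count
detections at the cutoff, and estimate

    FDR = π₀ · n̄₀ / n_AB,  π₀ = 1.

This is the standard expected-false-positives-over-discoveries
estimator for permutation/subsampling nulls; π₀ = 1 overestimates the
FDR slightly and is appropriate when detections are few relative to
all genes. When `n_AB = 0` the FDR is undefined and reported as NA;
values above 1 are reported as-is and flagged rather than truncated.
The 5%/95% percentile confidence bounds on `n̄₀` use linear
interpolation (quantile type 7, the numpy default). Seeding is
`base_seed + b` for null pair `b`, making every replicate independently
reproducible. Null score vectors are computed once and thresholded at
every cutoff when tracing FDR-vs-cutoff curves.

## Synthetic data

The generator realizes the motivating scenario — a regulatory module
co-expressed in one condition, disordered in the other — as
single-latent-factor modules: `x_g = sqrt(ρ_q) f_m + sqrt(1 − ρ_q) ε_g`
with `f_m, ε_g` i.i.d. standard normal per sample, giving *exact*
expected pairwise correlation `ρ_q` at O(genes × samples) cost.
Default design: one 20-gene module with ρ = 0.8 in A and 0 in B among
2000 independent background genes, 100 samples per group — a strong,
localized change against a clean background. Options: per-module
`de_shift` (mean offset in B, creating DE without DC), a global
background correlation, and a noise scale.

What the generator does *not* emulate: microarray technical artifacts
(probe effects, batch structure, normalization quirks), heavy-tailed
or skewed expression distributions, overlapping or hierarchically
correlated modules, and condition-specific variance changes. Passing
recovery tests on this model therefore demonstrates correctness of the
topology machinery and sensible statistical behavior, not performance
on real cohort data.

Hand-written toy fixtures (≤ 8 genes, ≤ 10 samples) provide fully
traceable cases: `identical` (both conditions equal — every score
null), `one_module_flip` (a 4-gene module whose rows are scrambled in
B), and `tie_case` (an exact mirror construction in which P-genes and
Q-genes receive identical score magnitudes in opposite directions).

## Evaluation procedures

- **Cross-validation reproducibility**: disjoint train and validation
  pairs are drawn without replacement per condition; a training
  top-fraction gene is validated if it reappears in the validation top
  fraction. Under unrelated rankings the expected overlap equals the
  validation fraction, which is the floor against which observed
  reproducibility is judged. Spearman correlation of the two score
  vectors is reported alongside. Membership, not direction, is
  validated.
- **DC vs DE**: per-gene Welch (unequal-variance) t-test with
  Benjamini–Hochberg step-up correction at 5% by default. Genes
  constant in both groups get p = 1 with a warning.
- **Cluster extraction**: agglomerative average-linkage clustering on
  the distance `1 − c`; the tree is cut at height `1 − r` so clusters
  are joined while their average Pearson correlation exceeds `r`
  (default 0.4). Cluster ids are ordered by size. Heatmap exports
  standardize each gene to mean 0, SD 1.

## Numerical conventions and degenerate inputs

- Pearson correlations are clipped to ±(1 − 1e−6) before `atanh`, so
  duplicated genes yield a large finite z (≈ 7.25) instead of ∞.
- Constant expression rows make correlation undefined and are rejected
  with the offending gene named; missing values are rejected at
  container construction.
- Correlations require > 3 samples per group (the Steiger variance
  needs `n − 3 > 0`); Welch needs ≥ 2.
- Probe-to-gene collapsing keeps the probe with the highest *mean*
  expression across samples (robust against single-sample spikes);
  ties go to the lexicographically smallest probe id.
- All ranked tables break score ties by gene id (stable sorts), so
  output is deterministic down to the byte.

## Problem sizes used in the shipped checks

The automated checks run the full algorithms at reduced scale chosen
for quick iteration: oracle-equivalence tests use ≤ 30 genes and ≤ 20
thresholds against literal reimplementations; the planted-module
recovery check uses the generator's default design (2020 genes, 100
samples per group) once per algorithm; null-calibration uses 150 genes,
30 samples per group and 25 null pairs over 20 repetitions. The
cohort-scale FDR summary values are recomputed from cohort-scale
inputs (mean null counts and detected-gene counts), since the
underlying 1317-sample multi-study cohort is not redistributed here.

## Known limitations

- The subsampling null mixes the two conditions, so when the groups
  truly differ the null is contaminated with real signal; the
  resulting FDR is conservative (biased upward), markedly so for lax
  cutoffs.
- DCglob's removal rule makes gene-level exclusivity depend on the
  whole component structure, so a gene's score can change when distant
  genes are added to the analysis.
- DCloc has no per-gene p-value; significance enters only through the
  subsampling FDR.
- Both algorithms are blind, by default, to sign flips of equal
  magnitude (`c → −c`) unless `absolute_correlation` is enabled, and
  to correlation changes confined to gene pairs (component size < 3 /
  neighborhood union < 3) — a deliberate focus on module-scale
  rewiring.
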
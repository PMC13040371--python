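# Methods

This note documents the statistical models implemented in `pidsle`, the
design choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Overlap enrichment

All gene sets are intersected with the declared universe before any
computation and the restricted sizes are reported, so discrepancies in
list provenance surface as auditable numbers instead of silent drops.
The Monte Carlo null draws `n` symbols uniformly without replacement per
iteration; `null_mean`/`null_sd` are the sample moments (sd with
denominator B−1, the unbiased choice) and the empirical p uses the
add-one (Phipson–Smyth) correction so it can never be zero at finite
iterations. The hypergeometric closed form is computed alongside every
simulation. When markers saturate the universe every draw ties the
observed count: the empirical p is 1 under the tie-inclusive counting
rule and the null sd collapses to 0, which is reported as a degenerate
result rather than an (undefined) z.

Implementation note: each iteration ranks i.i.d. uniform keys over the
universe and takes the `n` smallest, an exact uniform-subset draw that
vectorizes across iterations; memory is bounded by chunking.

## MCODE-style complex detection

Vertex weight = (highest k-core number of the node's closed
neighborhood) × (edge density of that k-core subgraph, `2E/(V(V−1))`,
no self-loops); vertices below the degree cutoff, or whose neighborhood
has no core of order ≥ 2, weigh 0. Expansion is breadth-first from
unvisited seeds in decreasing weight order, admitting unvisited
neighbors with weight ≥ seed-weight × (1 − node-score cutoff), to the
configured depth; nodes join at most one cluster. Post-processing:
haircut iteratively trims degree-1 members (on by default, fluff off);
multi-node candidates whose induced subgraph has no k-core of the
configured order are dropped; single-node candidates are emitted with a
`flagged` marker and excluded from enrichment and scoring, mirroring the
practice of discarding singleton complexes. Equal seed weights are
broken lexicographically on the symbol, which makes the output invariant
to node and edge input order.

**Planted-module recovery design.** The recovery study plants one
15-gene module (edge probability 0.9 inside, 0.01 elsewhere) in a
120-node background graph and measures the best-match Jaccard between
the planted membership and the recovered clusters over 20 generator
seeds; the median is ≥ 0.9. One module per graph is deliberate: with two
or more planted modules of equal density, any single cross-edge between
them (expected ≈ 2.25 between two 15-gene modules at p = 0.01) lets
threshold-based seeded expansion walk across, because the modules'
vertex weights are statistically identical and the node-score cutoff
cannot distinguish them. Multi-module graphs therefore measure a
property of the random-graph model, not of the detector; the disjoint
multi-module limit (p_between = 0) is covered separately.

## Moderated-t differential expression

Per-gene two-group linear model with pooled residual variance `s_g²`
(df `d_g = n₁ + n₂ − 2`). The prior `(d_0, s_0²)` is estimated by method
of moments on `e_g = log s_g² − ψ(d_g/2) + log(d_g/2)`:
`ψ'(d_0/2)` equals the excess variance of `e` (trigamma inverted by
Newton iteration), and `s_0²` follows from its mean. When the excess
variance is non-positive the prior df is infinite and the prior scale is
the arithmetic mean of the gene variances; the total df is capped at the
summed residual df. These choices make the statistic agree with the
reference R implementation (limma) to ~1e-14 on shared fixtures, which
the test suite verifies through Rscript in both the finite- and
infinite-prior regimes. Forcing `d_0 = 0` recovers the ordinary pooled
two-sample t; forcing `d_0 = ∞` the common-variance statistic.

Significance is the disjunction (unadjusted p ≤ 0.05) or (BH-adjusted
p < 0.2), both configurable. Probe dedup keeps the row minimizing
`(p, p_adj, probe_id)` — the probe id as final key makes the rule a
total order, hence deterministic and idempotent. Two significant lists
are merged after adjustment within each list (adjust-then-merge), then
deduped by the same rule.

## Module scoring

The single-sample score follows the GSVA recipe for log-intensity data:

1. kernel ECDF `z_ij = (1/S) Σ_k Φ((x_ij − x_ik)/h_i)` with
   `h_i = sd_i × 0.25` (a degenerate gene row falls back to a sharp
   kernel so equal values tie);
2. per sample, genes are ranked by `z` (average ranks on exact ties) and
   converted to the symmetric statistic `|r − (G+1)/2|`;
3. a random walk descends the ranked list (ties in walk order broken by
   gene symbol for bit-stable determinism), stepping up by the
   tau-powered rank statistic (normalized over module genes, tau = 1
   default) and down by `1/(G − m)` elsewhere;
4. the score is max-positive + max-negative deviation
   (`diff_of_extremes`, the reference default, range [−1, 1]) or the
   single largest-magnitude deviation (`max_deviation`, exposed for
   sensitivity analysis).

A module covering every matrix gene leaves no background for the walk
and is rejected; genes absent from the matrix are dropped with a
warning. The implementation is verified against an independent literal
loop transcription of steps 1–4 to 1e-10.

Stratification clusters samples with Euclidean distance and complete
linkage, cuts the tree to exactly k groups (k = 3 default), and relabels
clusters by first appearance in column order for determinism. Raw
scores are clustered by default; a `standardize_rows` flag z-scores
feature rows first, since whether to row-standardize before clustering
is a genuinely open choice. Clinical traits are compared across strata
with one-way ANOVA and Tukey HSD (studentized range); control samples
are excluded whenever the clinical table marks them; a trait constant
everywhere reports F = 0, p = 1 with a `constant` flag.

## Classification harness

Folds: every minority-class sample plus an equal-size majority subsample
drawn without replacement within the fold, so folds differ only in their
majority draw; each class is split 70/30 into train/validation inside
the fold. The nine classifier families come from scikit-learn at fixed
library defaults (recorded in `CLASSIFIER_FAMILIES`); the families
themselves are standard components, while the folds, confusion-matrix
metrics, ROC/PR curves (thresholds at every distinct score, trapezoidal
areas, precision 1 at the zero-recall endpoint) and permutation
importance (mean metric drop over shuffles of one column) are
implemented in-repo and tested against hand-worked examples and
scikit-learn cross-checks. Only binary contrasts are supported; degenerate
single-class validation splits are skipped with a warning and reported.

## Synthetic cohort generator

The generator's defaults describe a demonstration-scale study: 2,000
genes with 150 markers, 200 patients + 50 controls, three planted
20-gene modules with log2 effects (1.0, 0.5, 0.0) at full activity,
unit noise sd. Latent activity is 0 for controls, U(0, 0.4) for
inactive and U(0.5, 1) for active patients — chosen so the SLEDAI
threshold classes (active ≥ 6 with SLEDAI ≈ 12a + noise) are realizable
and separable at large effect sizes. Clinical traits are linear in
activity with additive Gaussian noise, clipped to positive ranges:
anti-dsDNA 20 + 180a IU, C3 1.1 − 0.5a g/L, C4 0.28 − 0.12a g/L, with
all coefficients exposed as config fields since only the directions of
these relationships are constrained by the application. Risk sets use
exponential-key weighted sampling without replacement (key =
Exp(1)/weight, keep the smallest), which is exactly uniform at odds 1 so
the null overlap is hypergeometric by construction. Each generator
consumes its own stream, seeded from the config seed by a fixed offset,
so adding a call to one generator never perturbs another's draws.

What the generator does *not* emulate: probe-level microarray
artifacts, batch effects, count noise, correlated co-expression outside
the planted modules, or realistic clinical-trait marginals (only
directions and rough magnitudes). Passing tests therefore demonstrate
that the statistical machinery is correct and calibrated under a clean
generative model, not that effect sizes of real cohorts are
recoverable at these sample sizes.

## Problem sizes used by the test and acceptance runs

Calibration uses 500 replicates of 1,000 genes at 10 vs 10 for the
moderated-t type-I rate, 200 replicates of 20 null modules at 25 vs 25
for the Welch/Hedges rate, 20 balanced folds of 300 permuted-label
samples, and 2,000 random scores for the AUROC null. The end-to-end
recovery study uses 20 seeds of a 500-gene, 250-patient + 50-control
cohort with ten 15-gene modules, one carrying effect 1 at noise sd 1;
the separable classification setting raises the effect to 3 at noise
0.3. The Monte Carlo/analytic comparison runs at the full 19,438-gene
universe with a 2,082-gene draw and 10,000 iterations. These sizes keep
every run deterministic and comfortably reproducible on a single CPU
while leaving the measured quantities stable to well within the asserted
tolerances.

## Known limitations

* MCODE cluster boundaries depend on the node-score cutoff relative to
  the weight spread; equal-density planted modules connected by even one
  edge merge (see the recovery-design note above).
* The empirical-p floor is 1/(B+1); strongly enriched overlaps saturate
  at that floor and are distinguished only by z.
* Hierarchical stratification with complete linkage is sensitive to
  score outliers; k is fixed by the caller, not selected.
* The classifier harness fixes library-default hyperparameters; it
  measures whether signal is present, not the best achievable accuracy.
* Multi-category gene annotations are not supported; the first tag wins
  with a warning.
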
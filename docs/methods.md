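# Methods

## The regulatory model

Each target gene is modeled independently.  With r candidate
regulators (given by the backbone network) and K samples,

log₂ yᵢ = log₂ xᵢ₀ + Σⱼ log₂((1 + Fⱼᵢ xⱼ)/(1 + xⱼ)),

a saturable Michaelis–Menten-like response per TF with multiplicative
(log-additive) combination across TFs.  The assumptions this encodes:
every TF acts independently on the promoter, the response saturates at
fold change Fⱼᵢ as the TF's expression grows, and expression is a
steady-state readout.  TF–TF cooperativity, miRNA/lncRNA layers, and
dynamics are deliberately outside the model.

**Fitting.**  The per-gene objective is
Σₖ(log₂ ŷₖ − log₂ yₖ)² + λ Σⱼ(log₂ Fⱼᵢ)², minimized over
(log₂ x₀, log₂ F) — optimizing in log₂ space guarantees F > 0 and makes
F = 1 (no regulation) the natural null.  Initialization: log₂ F = 0 and
log₂ x₀ = mean log₂ expression.  L-BFGS-B with analytic gradients
(∂log₂ŷ/∂log₂F = Fx/(1+Fx) per sample), gradient tolerance 1e-6, at
most 500 iterations; non-converged genes keep the last iterate and are
counted in `converged_genes`.  The basal level is fitted but
unpenalized, since the penalty's purpose is to damp extreme fold
changes, not overall expression scale.  λ defaults to 0.1, the value
selected by 5-fold cross-validation (sample-wise folds, mean held-out
sMAPE across genes) on cohort-scale data; the CV grid is
{0.01, 0.1, 1, 10}.

**Scale conventions.**  Inputs are nonnegative linear-scale expression
values (e.g. 2^RMA).  Zeros in observed target genes receive a
pseudocount of 1 before log₂ (microarray-like data has none; the
choice matters only for count-like inputs).  Standardized (z-scored)
expression is used exclusively for centroid classification, never as
regression input.

**Error metric.**  sMAPE = mean 2|ŷ−y|/(|y|+|ŷ|), with 0/0 defined as
0; bounded by [0, 2].  The inter-subtype matrix reports the median
sMAPE over the most variable genes (variance of log₂ expression within
the predicted cohort) and min–max scales each row, so each row shows
which model predicts that cohort best on a [0, 1] scale.

## Subtype signatures

The permutation null refits all subtype models on label-shuffled
cohorts (group sizes preserved) and records per-edge, per-subtype mean
and SD of log₂ F over 30 shuffles.  An edge is signature for a subtype
when |log₂ F − null mean| ≥ 5·SD (boundary included; SDs below 1e-6
are floored, and edges whose null SD is exactly zero are never called,
since a degenerate null carries no scale).  A TF is a subtype's
signature TF when more than half of its signature targets are unique
to that subtype; the participation score is the per-subtype fraction
of uniquely assigned targets, so rows sum to 1 exactly when no target
is signature in several subtypes.

A practical resolution limit, measured on synthetic cohorts: for a
planted subtype-unique edge the null SD is dominated by the variance
of mixture fits across shuffles, which scales like Δ/√n (Δ the log₂ F
shift, n the samples per subtype), while the deviation scales like Δ.
The z-statistic is therefore nearly independent of the planted effect
size and grows only with cohort size; at ~180 samples per subtype
(three-subtype cohorts of ~540 samples) mode-switching edges sit at
z ≈ 5–7, so recall at the 5-SD rule is high but sensitive to the
cohort draw, while the false-call rate on null cohorts is essentially
zero.  This is a property of the permutation scheme itself, not of the
implementation.

## Co-regulation

Profiles are log₂ F vectors over targets; targets with
|log₂ F| ≤ 0.1 for either TF are dropped (zero-inflation filter;
threshold configurable).  Outliers are flagged by RANSAC (seeded;
consensus sets of 80% of the points; residual threshold = MAD of the
residuals from an initial least-squares fit).  At most 20% of points
may be discarded: when RANSAC's consensus set is smaller, it is
expanded to the best-fitting 80% by absolute residual.  Without that
floor the inlier subset degenerates to the best-fitting half of the
data and unrelated profiles show |r| > 0.8 in ~1–3% of pairs; with it
the null rate is below 0.25% at 50 shared targets.  Pairs with ≤ 3
usable shared targets score exactly 0.  Enrichment against a reference
pair set uses Fisher's exact test on the top fraction by |r|;
recovery is summarized by a trapezoidal precision–recall AUC over all
unique |r| thresholds.

## Knockdown propagation (hPerturb)

The seed TF's expression is multiplied by the knockdown factor
(default 0, full silencing; factor 1 short-circuits to the baseline).
Every TF reachable in the TF→TF subgraph is then updated exactly once
by the forward model, from a queue keyed by the number of not-yet-final
regulators on the path from the seed.  Consequences of this schedule:
on acyclic graphs the result is bit-identical to a single pass in
topological order (diamond joins wait for all branches); feedback
edges to already-updated TFs are truncated; when a cycle leaves no TF
ready, the pending TF discovered earliest in breadth-first order is
released with its unperturbed regulators at baseline (deterministic
tie-break by name); self-loop TFs are never updated.  Non-TF targets
are recomputed last from final TF levels, and genes not downstream of
the seed are untouched.  Truncations are reported per run.

## Protein activity

Exponential Ranking on a signed, directed, likelihood-weighted
interactome.  The transition matrix is A = xxᵀ∘B (Aᵢⱼ = xᵢxⱼ·sign·w
for edge i→j) with μ = max A − min A over all entries, and the update
p ← exp((1/μ)Aᵀp)/‖·‖₁ — rank flows along edge direction.  The exp is
max-stabilized (identical after normalization), ‖p‖₁ = 1 after every
step, and iteration stops when the ℓ2 change drops below 1e-6 (at most
10,000 iterations; since μ scales with A, rescaling all weights leaves
the fixed point unchanged).  The start vector is the sample's
expression scaled to sum 1 when strictly positive, otherwise uniform;
the fixed point does not depend on it.  Final scores get a signed log
transform (ln p for p > 0, −ln|p| for p < 0, 0 stays 0), and activity
deltas are differences of transformed scores, perturbed − baseline.

## Essentiality models

Per TF: features are per-line activity deltas, standardized on the
training lines; response is the measured depletion score (more
negative = more essential).  Elastic net with penalty strength
log-spaced 1e-3…10 (7 points) × L1 ratio {0.1, 0.5, 0.9}, selected by
seeded 4-fold CV RMSE on a 75% training split (24 of 32 lines);
held-out lines never enter selection.  Subtype specificity of
predicted scores uses Welch's one-way analysis of means per TF, with
the most-dependent subtype defined by the minimum mean score.

An identifiability note: activity deltas for a given cell line are a
deterministic function of that line's TF expression vector, so the
feature matrix has intrinsic dimension at most the number of TFs.
Held-out *prediction* is therefore easy (r ≥ 0.8–0.98 on synthetic
chains), but identifying the exact sparse set of driver proteins is
not — sparse proxies predict identically, and no penalty choice can
separate them.  On full-rank features the same estimator recovers
100% of a 5-of-50 support at 24 training lines, which locates the
limit in the data geometry, not the estimator.

## Synthetic data: what it does and does not emulate

`generate_regulatory_truth` draws a bipartite TF→gene backbone at the
requested density with log₂ F uniform on ±[0.1, 2.5] (identifiable but
not extreme).  A configurable fraction of edges is "repurposed": the
subtype-unique value flips the sign of the shared log₂ F with
magnitude U[1, 2.5], i.e. an activation↔repression mode switch — the
phenomenon the signature analysis targets.  TF expression is exogenous
i.i.d. lognormal (log₂ mean 0, SD 1); targets follow the forward model
with additive Gaussian noise in log₂ space (default SD 0.1), matching
the least-squares objective.  Basal levels are lognormal around
2³ ≈ 8.  `simulate_essentiality` draws each TF's true drivers among
responsive proteins (delta SD ≥ 5% of that TF's largest column SD)
with a greedy pairwise-|r| ≤ 0.8 redundancy cap, then forms a sparse
linear score plus Gaussian noise.

Not emulated: read counts or probe-level noise, single-cell dropout,
TF autoregulation in generation, copy-number or mutation covariates,
and batch structure beyond a constant per-gene log₂ offset.  Passing
tests therefore demonstrate correctness of the algorithms and their
statistical calibration under the model's own assumptions, not
robustness to real-data artifacts outside them.

## Problem sizes and numerics

Tests and the acceptance script run scaled-down systems chosen to keep
each property measurable: regression recovery at 5 TFs × 20 targets ×
200 samples; signature calling at 4 TFs × 25 genes with three subtypes
of 180 samples (the permutation null needs cohort-scale groups, see
above); propagation and ranking oracles on 100/50 random graphs of up
to 30/50 nodes; the essentiality chain at 6 TFs × 40 genes × 32 lines.
Degenerate inputs are handled explicitly: empty binding tables pass
through thresholding; constant transition matrices, singleton batches,
sub-coverage centroid inputs, and single-subtype specificity tables
raise errors; constant genes are dropped from standardization with a
warning; ties (equidistant TSSs, equal centroid correlations, equal
group means) break deterministically and are surfaced in warnings.
Batch correction is location-only (per-gene batch-mean offsets in log₂
space, grand mean preserved) — an intentional simplification of
covariate-based linear batch models, adequate when no design
covariates are modeled.
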
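# tfregnet

Multilayer modeling of transcription-factor (TF) regulation for
molecularly heterogeneous tumors, built around glioblastoma-style
expression cohorts with subtype structure (e.g. Classical / Proneural /
Mesenchymal).  The package connects four layers:

1. **Regulatory parameterization.**  Starting from an unsigned
   candidate TF→gene backbone (motif binding scores near TSSs plus
   tissue regulatory networks), each TF–target interaction is assigned
   a *regulatory capacity* F by a thermodynamic nonlinear regression
   fitted per subtype:

   log₂ yᵢ = log₂ xᵢ₀ + Σⱼ log₂ ( (1 + Fⱼᵢ·xⱼ) / (1 + xⱼ) )

   where xⱼ is the linear-scale expression of TF j, xᵢ₀ the basal level
   of target gene i, and Fⱼᵢ the maximum fold change TF j can induce on
   gene i (F > 1 activation, F < 1 repression, F = 1 no effect).  The
   per-gene objective adds an L2 penalty λ·Σ(log₂ F)² and is minimized
   over (log₂ x₀, log₂ F) with L-BFGS and analytic gradients.

2. **Signatures and co-regulation.**  Subtype-specific ("repurposed")
   edges are called when an edge's log₂ F deviates from a
   label-permutation null (30 shuffles) by ≥ 5 standard deviations;
   TF–TF partnerships are scored by RANSAC-robust Pearson correlation
   of log₂ F profiles and benchmarked against known-interaction
   references (Fisher enrichment, precision–recall AUC).

3. **In-silico knockdown and protein activity.**  The recursive
   hPerturb algorithm silences a TF and propagates the change through
   the regulatory network, updating every TF at most once, deferring
   diamond joins until all on-path regulators are final, and truncating
   feedback loops.  Perturbed expression is overlaid on a signed,
   weighted protein interactome and scored by Exponential Ranking,
   p ← exp((1/μ)·Aᵀp) / ‖·‖₁ with A = xxᵀ∘B and μ = max A − min A.

4. **Essentiality prediction.**  Per TF, an elastic net (penalties
   chosen by seeded 4-fold CV on a 24/8 train–holdout split of cell
   lines) maps knockdown-induced protein-activity deltas to measured
   depletion scores and transfers them to new samples after
   nearest-centroid subtype assignment and linear batch correction.

A seeded synthetic-data layer generates ground-truth regulatory
systems, subtype cohorts (forward model + log₂-Gaussian noise), signed
protein networks, and sparse-linear essentiality scores, so the whole
pipeline is testable end to end without external data.

## Worked example

```sh
tfregnet simulate --n-tfs 4 --n-genes 12 \
    --subtypes Classical,Proneural,Mesenchymal \
    --samples-per-subtype 40 --seed 1 --out-dir sim
# -> wrote synthetic cohort to sim

tfregnet fit --backbone backbone.tsv --expression sim/expression.tsv \
    --subtype Classical --lambda 0.1 --out fvalues_classical.tsv
# -> fitted 12 edges (train MSE 0.01073, 100% genes converged)

tfregnet perturb --fvalues fvalues_classical.tsv \
    --expression sim/expression.tsv --tf tf000 --knockdown 0 --out kd_tf000.tsv
# -> 3 genes updated, 0 truncations
```

The fitted table stores one row per backbone edge:

```
tf      gene    subtype    F              log2F
tf003   g0000   Classical  3.60868624819  1.85147371573
tf000   g0002   Classical  1.19556916732  0.257697596769
```

`tf003` activates `g0000` (F ≈ 3.6: up to 3.6-fold induction at
saturating TF levels); the train MSE of 0.011 is the mean squared log₂
residual of the fit.  The knockdown output lists per-sample log₂ fold
changes of every updated gene; for the weak activation edge above the
target drops modestly, e.g.

```
gene    sample         log2fc
g0002   Classical_000  -0.308814635425
g0002   Classical_001  -0.160206697611
```

Other subcommands: `backbone` (assemble the candidate network from
BED-like binding scores and tissue networks), `classify`
(nearest-centroid subtype labels), `coreg`, `signatures`, `rank`
(Exponential Ranking activity scores), `essentiality train|predict`,
and `run` (the full demo pipeline with reproducibility manifests).

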
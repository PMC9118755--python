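# Methods

`magcnse` predicts lncRNA–disease associations (LDAs). Given a binary
association matrix `LD ∈ {0,1}^{L×T}` between `L` lncRNAs and `T` diseases,
lncRNA sequences and a disease-ontology DAG, it (1) builds five similarity
views, (2) learns one embedding per lncRNA and per disease from those views
with a multi-view GCN, channel attention and convolutional fusion trained on
an `LD`-reconstruction objective, and (3) classifies candidate pairs with a
two-level stacking ensemble.

## Similarity views

**Disease semantic similarity (DSS).** Wang's DAG method: each term `t` in
the ancestor closure `D(d)` of a disease `d` contributes
`DS_d(d) = 1`, `DS_d(t) = max{ξ·DS_d(t′) : t′ child of t in D(d)}` with
contribution factor `ξ = 0.5`. With `DC(d) = Σ_t DS_d(t)`,

```
DSS(d_i, d_j) = Σ_{t ∈ D(d_i)∩D(d_j)} (DS_{d_i}(t) + DS_{d_j}(t)) / (DC(d_i) + DC(d_j)).
```

The recursion is memoized over the closure, so it is linear in the number of
closure edges rather than exponential in path count. Diseases absent from
the DAG get zero off-diagonal similarity with a warning; the diagonal of
every view is forced to exactly 1 after evaluation, since floating-point
evaluation of an analytically-1 diagonal need not return 1.

**lncRNA functional similarity (LFS).** Best-match average of DSS between
the two lncRNAs' associated-disease sets `D(l_i)`, `D(l_j)` (sizes p, q):

```
LFS(l_i, l_j) = ( Σ_{d∈D(l_j)} max_{d′∈D(l_i)} DSS(d,d′)
                + Σ_{d∈D(l_i)} max_{d′∈D(l_j)} DSS(d,d′) ) / (p + q).
```

If either lncRNA has no associations the pair scores 0 (one warning).

**lncRNA sequence similarity (LSS).** Weighted Levenshtein distance with
substitution cost 2 and insertion/deletion cost 1 (so one substitution ties
a delete+insert), mapped to `LSS = 1 − dist/(len_i + len_j)`. The DP kernel
is compiled with numba; because no installed library supports non-unit
substitution costs the DP is implemented here directly. With these costs the
value is symmetric in its arguments and always lands in [0, 1].

**Gaussian interaction-profile kernels (LGS, DGS).** Profiles are `LD` rows
(lncRNAs) or columns (diseases); the bandwidth is
`η = 1 / mean_i ‖profile_i‖²` (numerator fixed at 1, no override) and
`sim(i,j) = exp(−η‖profile_i − profile_j‖²)`. An all-zero matrix leaves the
bandwidth undefined and is a hard error.

## Representation learning

Each view `S` becomes a graph with normalized adjacency
`Ñ = D̃^{-1/2}(I+S)D̃^{-1/2}`, `D̃(i,i) = Σ_j (I+S)(i,j)` (always well
defined because the diagonal is 1). Per view, a GCN propagates

```
X^(l+1) = ReLU(Ñ X^(l) W^(l)),    X^(0) random,
```

with `F = 128`-dimensional embeddings and 2 layers by default. The per-view,
per-layer outputs, transposed to `F×n`, form `C_in` channels in a fixed
order (lncRNA views LFS, LSS, LGS; disease views DSS, DGS; inner order layer
1..l) — the order must be canonical because the attention and fusion
parameters are channel-indexed.

**Channel attention.** Squeeze-excitation: `z_k` is the global mean of
channel k; gates are `σ(W₂ ReLU(W₁ z))` with `W₁ ∈ R^{Cμ×C}`,
`W₂ ∈ R^{C×Cμ}`, expansion `μ = 5`, no bias on either map; channel k is
multiplied by its gate.

**Convolutional fusion.** `C_out = 128` filters, each `F×1`, shared across
input channels: output channel q at entity j is
`Σ_i ⟨channel_i[:,j], w_q⟩ + b_q` — an F-length valid convolution down the
feature axis that collapses it, yielding the final `C_out×n` representation.

**Objective and optimizer.** `LD′ = X′ᵀY′`; the loss is the squared
Frobenius norm `Σ (LD′−LD)²` over unmasked cells. All parameters — initial
embeddings, GCN weights, attention weights, filters and biases — are
trained jointly with Adam (lr 0.001, β = 0.9/0.999) for 250 epochs.
Initialization is Glorot-uniform (zero biases), derived from a single seed;
training is float32 and bit-reproducible on a fixed platform. Similarity
math stays in float64. No dropout or weight decay is used. The trainer is
plain numpy with analytic gradients (the graphs are dense and tiny, a few
hundred nodes, so this is both simpler and faster than a tensor framework);
gradients were validated against central finite differences during
development and the forward pass is tested against the standalone
normalize/propagate/attend/fuse operations.

**Ablation variants** (config flags): `first_layer_only` keeps only each
view's first-layer channels; `use_attention=False` gives all channels unit
gates; `use_cnn=False` replaces fusion with the channel-wise mean, giving an
`F×n` embedding (the fusion rule for the no-CNN variant is not uniquely
determined by the model description; the mean is this package's reading).

## Pair classification

Positive pairs are all 1-cells of `LD`; negatives are an equal-sized
uniform, seeded sample of 0-cells (optionally excluding a disease under
case study). A pair's feature vector concatenates its lncRNA and disease
embedding columns (2×128 = 256 dims by default).

Five tree-based base learners — RandomForest, ExtraTrees, XGBoost, LightGBM
and a histogram gradient-boosting machine — are each trained with internal
stratified 5-fold CV; the out-of-fold predicted probabilities form five
meta-feature columns (every training row is predicted by a fold model that
never saw it, which the tests verify by refitting from the stored fold
bookkeeping). A logistic regression (C = 20, L2) is fit on the meta-features.
At prediction time each learner's five fold models are averaged, then the
logistic head combines the five averages; the label threshold is 0.5 (a
choice this package fixes; nothing in the model prescribes it).

The histogram gradient-boosting learner is configured in the same parameter
ranges as the published CatBoost column (depth 3, 800 iterations, lr 0.1,
32 bins, L2 = 5); it is the same algorithm family and plays the same role in
the ensemble. The `reference` hyperparameter profile carries the published
tuning (2000 trees for the forests, 1000 XGBoost rounds, …), sized for the
curated ~1600-association dataset. For the 100×50 synthetic benchmarks the
`compact` profile (≈100–150 trees per learner) is used: on ~850 pairs the
extra capacity measurably changes nothing but the runtime, and the tests and
the acceptance script run dozens of fits. Grid search is supported in
principle by editing the profile dictionaries but is off by default —
reproducibility over silent search spaces.

## Evaluation

Threshold metrics (accuracy, sensitivity, specificity, precision, F1, MCC)
come from the confusion table at the 0.5 cut; a zero denominator makes the
metric *undefined and flagged*, never 0. AUC is the Mann–Whitney statistic
(ties ½), AUPR the precision–recall step integral; both are checked against
exhaustive brute-force oracles.

**Cross-validation and transduction.** `cross_validate` runs repeated
stratified k-fold CV (default 5×5) of the entire pipeline on the balanced
pair set. Two protocols are supported:

* `leakage_safe=True` (library default): for every fold, the held-out cells
  are zeroed out of `LD` before the GIP and functional views are computed
  and masked out of the reconstruction loss, and representations are
  re-trained per fold. No test information can reach the embeddings.
* `paper_faithful` (`leakage_safe=False`): views and representations are
  computed once from the full matrix, as in the published pipeline order,
  and only the classifier respects the fold split. This is transductive:
  held-out positives influence the embeddings through the GIP profiles and
  the loss.

The distinction matters quantitatively. On the synthetic benchmark the
strict protocol is information-capped: a scorer with perfect knowledge of
the planted blocks reaches only AUC ≈ 0.85–0.86 on held-out balanced cells,
because a held-out within-block positive is statistically exchangeable with
a within-block negative. The pipeline's leakage-safe AUC (≈ 0.7) therefore
cannot approach 1 no matter how good the model is, while the transductive
protocol reaches ≈ 0.9. The recovery, ablation and stacking benchmarks are
run under the transductive protocol — the protocol the original MAGCNSE
evaluation uses; the acceptance script reports both.

**Case studies.** `rank_candidates` implements two protocols for a chosen
disease: *unknown_only* trains on all known positives plus matched negatives
that never involve the disease, then scores only the disease's unknown
pairs; *leave_disease_out* first deletes all of the disease's associations
(treating it as a new disease) and scores every lncRNA against it. Ties are
broken by score descending then lncRNA id ascending, so rankings are
deterministic.

## Synthetic data

The generator emulates the three real inputs at desk scale with a planted,
recoverable ground truth. lncRNAs and diseases are partitioned into
`n_blocks` matched blocks; `LD(i,j) ~ Bernoulli(p_in)` within matched blocks
and `Bernoulli(p_out)` otherwise, resampled (up to 100 times) until no
entity is isolated. Each lncRNA block descends from a random ancestor
sequence by per-site substitutions (substitution-only keeps lengths equal,
which keeps the LSS denominator simple), so LSS carries block signal. Each
disease block owns a distinct subtree under a shared root (depth 3,
branching 2 by default), so within-block Wang similarity exceeds cross-block
analytically. The benchmark family is 100×50 with 4 blocks, `p_in = 0.3`,
`p_out = 0.01`, 200 nt sequences at 10% mutation — sizes chosen so the full
pipeline (including per-fold retraining) runs in minutes on one core while
leaving the block signal clearly recoverable.

What the generator does **not** emulate: the heavy-tailed degree
distributions of curated association databases, shared ancestry *between*
disease blocks, sequence length variation, and indels. Passing the recovery
tests therefore demonstrates that the machinery extracts planted multi-view
block structure end-to-end, not that it attains any particular performance
on curated data.

## Numerical choices and degenerate inputs

* Similarity matrices are symmetrized (`(S+Sᵀ)/2`), clipped to [0,1] and
  given an exact unit diagonal on construction; views must match the
  association matrix's entity order exactly or construction fails.
* Symmetry tolerance for accepting a view is 1e-12; oracle-equivalence
  tests use 1e-10.
* Matrix TSVs are written with 17 significant digits, so float64 round-trips
  are exact.
* An all-zero association matrix (GIP undefined), a missing sequence
  (sequences were a filtering criterion upstream, so absence is a data
  error), cycles in the ontology, and non-finite training losses are all
  hard errors; a disease missing from the DAG degrades gracefully to
  identity-only similarity.
* Seeds: one top-level seed fans out to stage seeds by fixed offsets
  (`pipeline.SEED_OFFSETS`); all derived seeds stay below 2³¹.

## Known limitations

* The numpy trainer is single-machine, full-batch and dense — appropriate
  up to a few thousand entities, not beyond.
* The leave-one-disease-out protocol retrains everything per disease; at
  database scale that is hours, not seconds.
* Probabilities from the stack are not calibrated; the 0.5 threshold is a
  convention, and ranking metrics are the primary outputs.
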
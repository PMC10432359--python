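# Methods

This note documents the models and procedures implemented in `autocdrp`,
the parameter choices that matter, what the synthetic layer does and does
not emulate, and the numerical decisions taken where the design was open.

## Search space and sampling

The default space (`space.default_space`) has twelve components: seven
per-layer architecture functions (aggregation {add, mean, max}, convolution
{GCNConv, GENConv, GINConv, SGConv, Linear}, dropout {off, 0.2, 0.4, 0.6},
activation {Softplus, identity, ReLU, PReLU, sigmoid}, normalizer
{BatchNorm, GraphNorm, none}, hidden width {16, 64, 128, 256}, multi-head
{1, 2, 4, 6, 8}) and five global training hyperparameters (learning rate,
weight regulation, optimizer, loss criterion, pooling). With two layers the
per-layer components contribute `(3·5·4·5·3·4·5)² = 18000²` combinations and
the global ones a factor 96, i.e. 3.1104×10¹⁰ architectures over `q = 42`
options. Counting uses exact integers throughout.

Controlled stratified sampling fixes each of the `q` options in turn and
draws `m = ceil(n/q)` architectures containing it (for a per-layer option
the pinned layer is uniform). `ceil` generalizes the divisible worked
example (n = 300, q = 50 → m = 6) and guarantees `q·m ≥ n`. Collisions
between strata are resolved by bounded rejection (≤ 100 redraws per slot,
preferring descriptors not yet sampled); any residual duplicates are
dropped, so the final sample has at most `q·m` distinct descriptors and
every option retains its coverage floor whenever the space is large enough
to permit it. A `uniform` sampler (independent draws, deduplicated) is also
provided; it is used both as the random-search baseline's generator and for
budgets below `q`, where stratified coverage is impossible by construction.

## DAG encoding

An architecture is encoded as a directed acyclic graph with one node per
(per-layer component, layer) pair plus one node per global component — 19
nodes for the default space. Node features are one-hot over the shared
`q`-option vocabulary (an option chosen in two layers yields two nodes with
identical feature rows, distinguished by topology). Edges are fixed by the
space, not the choices: within layer ℓ the sub-module choices point at the
convolution (aggregation→conv, hidden→conv, multi-head→conv), data flows
conv→activation→normalizer→dropout, layers chain through
dropout(ℓ)→conv(ℓ+1), and dropout(L)→pooling; on the training side,
learning-rate→optimizer, weight-regulation→optimizer, and
pooling→loss-criterion ← optimizer, making the loss criterion the unique
sink. Where the optimizer and loss nodes attach is not uniquely determined
by the data-flow principle; this scheme is one consistent reading, chosen
so the graph has a single sink and every node lies on a path to it. For
non-default component sets a generic chain scheme (per-layer components in
space order, then globals) keeps the encoding total. `decode(encode(d)) = d`
holds for every valid descriptor.

## Surrogate model

The performance predictor is a two-layer GIN-style network adapted to
directed graphs:

    h_v^(l) = PReLU( W_l · Σ_{u ∈ N_in(v)} h_u^(l−1)  +  B_l · h_v^(l−1) )

with in-neighbor aggregation (messages follow edge direction; an optional
bidirectional mode is off by default), a learnable scalar PReLU slope per
layer, mean readout over nodes, and a two-layer fully connected head with a
scalar output. The self-loop term `B_l h_v` is read as an additive
contribution inside the activation; the alternative reading (a vector-valued
activation slope) is ill-typed. `W_l` acts on the aggregated message by
matrix–vector product; an elementwise product would force the hidden width
to equal `q`.

Training minimizes the batch smooth-L1 loss: per element,
`0.5 e²/β` if `|e| < β` else `|e| − β/2`, averaged over the batch
(β = 1; the two branches agree at `|e| = β`, so the loss is continuous).
Defaults: Adam, learning rate 1e-5, L2 regularization 5e-4, 500 epochs,
random 80/20 train/test split. Hidden width (64) and batch size (32) are
free choices.

**Label standardization.** Measured validation RMSEs live on a ~1e-2 scale.
On that raw scale the loss gradients are two orders of magnitude below both
the smooth-L1 threshold and the weight-decay term, and training collapses
to predicting the label mean. `fit` therefore standardizes labels (z-score
on the training split) before optimization and maps predictions back; the
final head layer is initialized small so initial predictions sit at the
label mean. This is a conditioning change only — all hyperparameters above
are applied as stated, on the standardized scale.

Ranking quality is reported as RMSE, Pearson r and Kendall τ (τ-b tie
handling, via scipy). Zero-variance inputs are flagged as degenerate rather
than silently returning NaN correlations.

## Candidate CDRP models

`build_model` instantiates any descriptor as a two-branch regressor:

- **Drug branch** — two searched convolution layers over the molecular
  graph. Operators: GCNConv (symmetric-normalized propagation with
  self-loops), GINConv (`(1+0)·h + aggregated neighbors`, then linear),
  SGConv (two normalized propagation hops, then linear), GENConv
  (ReLU-positive messages, aggregation, two-layer MLP; a simplified variant
  of the generalized convolution), Linear (per-node transform, ignores
  edges). The aggregation choice {add, mean, max} configures the
  neighborhood reduction for GIN and GEN; for GCN/SGConv/Linear the
  reduction is fixed by the operator and the choice is recorded but inert
  (logged). Multi-head k runs k parallel operator instances and averages
  them; k = 1 is a single branch. Activation, normalizer (BatchNorm over
  the node batch, GraphNorm per graph) and dropout follow each convolution.
  The searched pooling (add or max) produces the drug embedding.
- **Cell branch** — fixed two-layer fully connected encoder (735 → 256 →
  128, ReLU); the search space covers only the graph branch.
- **Head** — concatenation → two fully connected layers → sigmoid, so
  predictions lie in (0, 1), matching min–max-normalized ln(IC50) targets
  (training-split min→ε, max→1−ε, ε = 1e-6, invertible).

Candidates are trained with MSE on the normalized targets. The space's
loss-criterion component (CrossEntropyLoss/NllLoss) is ill-typed for scalar
regression and is retained only as a descriptor/encoding feature — a known
inconsistency in the space definition. Optimizer, learning rate and weight
regulation come from the descriptor's global choices. The searched
activation/normalizer apply only to the two searched convolution layers,
not to the head. Validation RMSE from `train_eval` is the surrogate's
ground-truth label.

Splits: `mixed` shuffles interaction pairs (default 80/10/10);
`blind_drug`/`blind_cell` partition drug (cell) identities instead, so no
entity appears in two partitions — the cold-start setting.

## Synthetic layer

The fitness oracle is a deterministic map descriptor → pseudo-RMSE:
`base + Σ active option weights + Σ active pairwise interaction weights
(+ seeded noise)`, clamped at ≥ 0. Per-layer options count once per layer
they appear in. Defaults: base 0.08, option weights N(0, 0.005²),
10 cross-component interaction pairs N(0, 0.01²) — values spread over
roughly 0.02–0.14, the scale of validation RMSEs on normalized targets.
The sparse interactions make the landscape non-additive, so a linear probe
on option indicators cannot solve it exactly. Noise, when enabled, is a
pure function of (descriptor, oracle seed) via a CRC-derived stream, so the
oracle remains deterministic.

The dataset generator emulates processed drug-panel shapes: drugs are
random connected molecular-like graphs (random tree plus a few extra edges,
degree ≤ 4) with structurally valid 78-D atom features (symbol/degree/
H-count/valence one-hot blocks + aromaticity flag); cells are Bernoulli(0.5)
binary 735-D vectors; ln(IC50) is a planted linear function of the drug's
mean feature vector and a 20-column cell-feature subset plus Gaussian noise
(default sd 0.1). With zero noise the planted function is exactly
recoverable (R² = 1 ceiling). What this does **not** emulate: real chemical
constraints (rings, valence rules beyond the degree cap), correlated
mutation/CNV structure across cell lines, heavy-tailed IC50 marginals, or
drug–cell interaction effects beyond additivity. Passing tests therefore
demonstrate the machinery (coverage, encoding, surrogate ranking, selection)
under controlled signal, not state-of-the-art accuracy on real panels.

## Search loop

`run_search`: stratified sample (budget `n_train_archs`, default 800) →
evaluate each architecture (oracle, or candidate training at
`candidate_epochs`, default 200) → fit surrogate → draw the candidate pool
(default 10⁶ uniform seeded draws — the full space is far larger, so the
"all architectures" stage is necessarily a subsample; deduplicated against
the training set, or supplied explicitly for enumerable spaces) → predict →
select top-k (default 100, lowest predicted RMSE, ties broken by canonical
serialization) → re-evaluate the k finalists at `final_epochs` (default
300) → report the true argmin. Exactly `|T| + k` true evaluations are
performed and logged. Candidate-level failures are logged and skipped,
never imputed. A single surrogate pass is used (no iterative refinement).
`run_random_search` evaluates `n_train_archs + k` uniform draws — the same
total budget — and reports the argmin. The selection direction is
minimization throughout, since the surrogate predicts an error.

## Problem sizes in tests and the acceptance script

Desk-scale runs use reduced sizes chosen once: ranking recovery trains on a
300-budget stratified sample and scores 100 fresh architectures (three
seeds); the search-versus-random comparison uses n = 300, k = 50, pool
1500 over ten seeds; exhaustive-equivalence uses a 256-architecture
enumerable space with the whole space as the pool; the end-to-end
candidate-training run uses 10 drugs × 30 cells, five training
architectures (uniform sampler — below `q`, stratified coverage is
impossible), k = 2 and 5 epochs. These sizes exercise every stage of the
pipeline while keeping runs to minutes on one CPU.

## Numerical choices and limitations

- All numerics are float64 on the package's own reverse-mode autodiff layer
  (`autocdrp.nn`); every source of randomness is an explicit
  `numpy.random.Generator` seed, so runs are bitwise reproducible.
- BatchNorm uses the statistics of the node batch it is given (no running
  averages); evaluation passes are full-batch, so metrics are deterministic.
- Segment-max pooling routes gradients to every row attaining the maximum.
- GENConv and multi-head are simplified readings: the space names the
  options but not their construction for these operators.
- Blind splits guarantee at least one entity per partition, so tiny datasets
  may deviate from the nominal fractions.
- The surrogate offers no uncertainty estimates; top-k selection is purely
  greedy on predicted RMSE.
- Results on real GDSC/CCLE panels (mixed/blind-test PCC and RMSE of
  trained candidates) require the original data and GPU-scale training and
  are outside what this package computes.
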
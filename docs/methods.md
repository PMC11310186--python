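# Methods

## Problem setting

Each hospital/ICU encounter is a node carrying a feature vector of binary
medical-code indicators (diagnoses, treatments) and a few numeric
covariates, plus a binary outcome label (e.g. in-hospital mortality).
Outcome prevalence is low (order 10 %), so AUPRC — whose uninformative
baseline equals the prevalence — is the evaluation metric throughout.
Time-series structure within an encounter is deliberately ignored: one
encounter, one node, one feature vector.

## Pipeline and assumptions

**Similarity graph.** Edge (i, j) exists iff cos(x⃗ᵢ, x⃗ⱼ) > t, strict, with
t = 0.85 by default. Strictness means ties at exactly t produce no edge. The
graph is stored undirected: the cosine kernel is symmetric and cannot orient
an edge. Similarities are computed blockwise on row-normalised features so
the dense N×N similarity matrix never exists in memory; only supra-threshold
pairs are materialised. Zero-norm rows and NaNs are hard errors, because
they indicate a failed imputation upstream, not legitimate isolated
patients. Whether to standardise features before the cosine is genuinely
open; the default computes on imputed, unstandardised features (binary
indicators already share a scale), with a `standardize` flag for z-scoring.

**Clique weighting.** Maximal cliques are enumerated by Bron–Kerbosch with
pivoting (pivot maximises |P ∩ N(pivot)|, ties to the lowest index); output
is normalised — cliques internally sorted, then sorted lexicographically —
so enumeration order is reproducible. Isolated nodes appear as singleton
maximal cliques. An edge in a (c+1)-clique gets weight c. When a pair
belongs to several maximal cliques the aggregator is **max** by default: it
rewards the strongest community containment and keeps weights bounded by
ω(G) − 1; `sum` and `count` are available since the choice is genuinely
underdetermined. Weighting operates on the binary support and resets
previous weights, so it is idempotent, never changes the edge set, and every
edge keeps weight ≥ 1. A SHA-256 digest of the edge set binds a clique set
to the graph it came from; re-weighting a different graph with a stale
clique set is an error.

**Encoder.** MP(H, A) = ReLU(D̂⁻¹ Â H Θ) with Â = A + I; self-loops always
have weight 1 (clique weights never apply to them), guaranteeing positive
degrees and making each row of D̂⁻¹Â a convex combination. Two MP layers,
both 16-dimensional, both with ReLU (including the final layer; the head
operates on the rectified embedding). The classification head is the
minimal one consistent with node classification: a single linear map +
sigmoid, scores clamped to [1e−7, 1 − 1e−7] before logarithms. Parameters
use seeded Glorot-uniform initialisation. No dropout or hidden nonlinearity
beyond the two MP ReLUs is added. Forward, backward (hand-derived chain
rule through both layers, pushing gradients through the propagation with
Pᵀ) and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8, no weight decay) are NumPy;
analytic gradients match central finite differences to < 1e−4 relative
error in the tests (observed ~1e−8).

**Edge flux.** Per epoch, each unordered absent pair gains an edge with
probability p_add (weight 1) and each present edge is deleted with
probability p_delete; decisions are mirrored, keeping symmetry. Flux is
always applied to the pristine clique-weighted graph — compounding across
epochs would drift the edge density toward the p_add/(p_add + p_delete)
fixed point. Cliques are not re-enumerated for perturbed graphs: the
enumeration cost would dominate training and added edges are transient
noise by design. Additions are sampled by drawing Binomial(#absent, p_add)
and then choosing that many distinct absent pairs uniformly
(distributionally identical to per-pair Bernoulli, without an O(N²) scan);
a dense fallback enumerates absent pairs exactly when most of them will be
added. The randomness stream is a pure function of (seed, epoch). Defaults
p_add = 0.01, p_delete = 0.05 keep the expected perturbation a small
fraction of |E| on sparse graphs; no published values exist to compare
against, so both are exposed as configuration.

**Training and evaluation.** Adam, learning rate 0.001, batch size 128,
250 epochs by default. Batch semantics for a full-graph model: every step
computes embeddings on the whole (perturbed) graph, while the mini-batch
selects which training labels enter the BCE — the simplest reading
consistent with transductive message passing. Evaluation is transductive:
validation/test features participate in message passing, their labels never
touch training or model selection (an inductive held-out-subgraph mode is
future work). Splits are uniform node partitions with largest-remainder
rounding; the "patients never shared across splits" guarantee is honoured
at encounter level, since no patient-to-encounter mapping exists here
(limitation). Per repeat, the checkpoint with best validation AUPRC is
kept; an experiment reports mean ± std test AUPRC over n_repeats = 5
repeats with independently drawn splits/initialisation/flux. A master seed
spawns named sub-streams (splits, init, flux, batching) via CRC-tagged
SeedSequences, so ablation arms differ only in the ablated component:
with p_add = p_delete = 0 the full and no-edge-flux arms are bit-identical,
and the no-clique arm is exactly a run with all edge weights forced to 1.
AUPRC is the average-precision step-curve sum (tied scores grouped into one
threshold), delegated to scikit-learn behind the module surface and checked
against a hand-written threshold sweep to 1e−10; single-class inputs are
rejected.

## Synthetic cohorts

The generator emulates the statistical shape of preprocessed ICU cohorts:
~12 active codes per encounter drawn from a cluster prototype, a handful of
numeric covariates, ~15 % positives, optional missingness. Each of K
clusters owns a disjoint set of 12 codes (drawn without replacement from a
120-code vocabulary), so between-cluster cosine similarity is near zero
while within-cluster similarity is high — the 0.85 threshold then recovers
the latent groups. Per-encounter noise toggles each prototype code off with
probability `code_noise_rate` (default 0.05) and activates an
expected-matching number of background codes. Numeric covariates are
Gaussian around cluster means with spread small relative to the code-block
norm. Labels follow the cluster's dominant label with probability
`cluster_outcome_strength` (default 0.9), otherwise Bernoulli(positive
rate); dominant-positive clusters are chosen greedily so their member share
best approximates the target rate, which keeps the realised prevalence
within cluster granularity (< 1/(2K)) of the target, and makes labels
exactly independent of clusters at strength 0. Missing cells are NaN — an
explicit not-a-value marker that cannot collide with a legitimate code —
and imputation is observed-mean (numeric) / observed-mode (categorical,
ties to the smaller value); binary code indicators are treated as
categorical. What the generator does **not** emulate: real marginal code
frequencies, code co-occurrence beyond cluster structure, visit sequences,
and the raw-EHR preprocessing steps (duration filtering, code
de-duplication) that operate on timestamps the package never sees. Passing
tests therefore demonstrate correctness of the machinery and learnability
under controlled structure, not clinical performance on real EHR data.

## Numerical and scale choices

Problem sizes in the tests and the acceptance script — cohorts of 200–500
encounters, graphs of ≤ 50 nodes for distributional checks, 2,000 flux
draws — are chosen so the full suite completes in minutes on one CPU while
every statistical band (4σ for the flux edge-count expectation, 3 SE for
prevalence) retains power. Exhaustive-subset clique oracles run at n ≤ 12
(4,096 subsets). Permutation equivariance of the encoder holds up to float
summation reorder (~1e−16; asserted at 1e−12), and the propagation rows sum
to 1 within 1e−9 as guaranteed by construction. Degenerate inputs are
defined, not accidental: edgeless graphs give singleton cliques and a
per-node MLP encoder; constant-label cohorts are rejected before training;
a NaN loss aborts with epoch/batch diagnostics.

## Known limitations

- Transductive only; no inductive evaluation on held-out subgraphs.
- Encounter-level splits cannot enforce patient-level disjointness.
- Clique weights are not refreshed after edge flux within an epoch.
- p_add/p_delete defaults are package choices, not validated against any
  published experiment.
- The generator's binary-indicator features cannot represent count-valued
  codes.
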
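# cliqueflux

Graph-based outcome prediction for electronic health records (EHRs). The
package turns a matrix of patient encounters (sparse binary diagnosis and
treatment code indicators plus numeric covariates) into a patient-similarity
graph, strengthens edges inside tightly knit patient groups via maximal
cliques, and trains a small graph neural network — regularised by stochastic
edge perturbation — to predict a binary outcome such as ICU mortality or
readmission. It is aimed at clinical-informatics researchers who want a
tested, fully reproducible reference pipeline that runs end to end on
synthetic cohorts, with no access to credentialed EHR databases required.

## The model

Given encounter features **X** ∈ ℝ^{N×F} with binary labels *y*:

1. **Graph construction.** Encounters *i*, *j* are joined by an edge when
   the cosine similarity k(x⃗ᵢ, x⃗ⱼ) = x⃗ᵢ·x⃗ⱼ / (‖x⃗ᵢ‖‖x⃗ⱼ‖) strictly
   exceeds a threshold (default 0.85). The graph is undirected.
2. **Clique weighting.** All maximal cliques are enumerated with the
   Bron–Kerbosch algorithm (with pivoting). An edge whose endpoints share a
   maximal clique of size c+1 gets weight A_ij = c; when several cliques
   contain the pair, the largest wins (max aggregator; sum/count are options).
3. **Encoder.** Two mean-pooling layers
   MP(H, A) = ReLU(D̂⁻¹ Â H Θ), with Â = A + I and D̂ the degree matrix of
   Â, produce F′ = 16-dimensional embeddings; row i of D̂⁻¹Â is a convex
   combination over i's closed neighbourhood, so clique weights act as
   aggregation weights. A linear layer + sigmoid head scores each encounter,
   trained with binary cross-entropy.
4. **Edge flux.** Once per epoch the pristine weighted adjacency is
   perturbed: each absent pair gains an edge with probability p_add, each
   present edge is dropped with probability p_delete. This regularises
   training and accounts for unobserved patient similarities.
5. **Evaluation.** AUPRC (area under the precision–recall curve) on held-out
   encounters, under repeated random train/validation/test splits
   (70/15/15 down to the data-scarce 20/40/40 regime), selecting the epoch
   with the best validation AUPRC per repeat and reporting mean ± std.

Because the real MIMIC-III / eICU inputs are credentialed, the package ships
a synthetic cohort generator that reproduces their statistical shape —
sparse per-cluster code prototypes, ~7–17 % positive outcomes, missing
values — with known latent structure, so every stage is testable. Mean
(numeric) / mode (categorical) imputation is applied before graph
construction. The encoder, its analytic gradients and the Adam optimiser are
implemented directly in NumPy/SciPy and verified against central finite
differences.

## Worked example

```bash
cliqueflux generate --n-encounters 400 --missing-rate 0.05 --seed 7 --out cohort.csv
cliqueflux build-graph --cohort cohort.csv --out graph.tsv
cliqueflux cliques --graph graph.tsv --out cliques.txt --weighted-out weighted.mtx
cliqueflux train --cohort cohort.csv --epochs 100 --n-repeats 5 --splits 40/30/30 \
    --seed 7 --out-dir run
```

prints

```
wrote 400 encounters x 124 features (66 positives, 2416 missing cells) to cohort.csv
graph: 400 nodes, 5625 edges (threshold 0.85) -> graph.tsv
334 maximal cliques (largest 32) -> cliques.txt; weighted graph -> weighted.mtx
[full] test AUPRC 0.8741 +/- 0.0667 over 5 repeats -> run
```

The cohort has 16.5 % positive outcomes (66/400) and a missing-cell rate of
~5 %. The 0.85 cosine threshold recovers the latent patient groups: the 334
maximal cliques (largest of size 32) sit almost entirely within clusters.
Training on 40 % of labels and evaluating on the held-out 30 % test split
yields a mean AUPRC of 0.874 — far above the 0.165 prevalence baseline an
uninformative classifier would score. `run/` contains `results.json`
(per-repeat AUPRCs, mean ± std), `training_log.jsonl` (per-epoch losses and
validation AUPRC) and `manifest.json` (resolved configuration and input
digests). `cliqueflux ablation` runs the full, no-edge-flux and no-clique
arms side by side; `cliqueflux evaluate` pretty-prints a saved result.

Everything is also available as a library:

```python
from cliqueflux import (CohortSpec, generate_cohort, impute, build_graph,
                        enumerate_maximal_cliques, assign_clique_weights,
                        TrainConfig, run_experiment)

cohort = impute(generate_cohort(CohortSpec(n_encounters=500, seed=0)))
result = run_experiment(cohort, TrainConfig(split_fractions=(0.4, 0.3, 0.3), seed=0))
print(result.mean_auprc, result.std_auprc)
```

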
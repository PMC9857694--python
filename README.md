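# emaplex

Reconstruction of sparse, undirected, unweighted **multiplex networks**
from partial observations, by **expectation–maximization with interlayer
aggregation (EMA)**.

Multiplex networks — one shared node set, several layers of relations —
arise wherever the same actors interact through different channels:
co-offending vs. kinship ties in covert networks, electrical vs. chemical
synapses in a connectome, transit modes in a transport system. Mapping
such networks is rarely complete: whole nodes go unobserved, and with them
every link they carry. `emaplex` infers the hidden part of each layer and
is aimed at network scientists, computational criminologists and systems
biologists who need a principled completion of partially mapped
multilayer data.

## The model

Each layer ℓ is modeled by the configuration model with degree sequence
d^ℓ and edge count |E^ℓ|: the prior probability of a link between nodes
i and j is

    p_ij^ℓ = min(1, d_i^ℓ d_j^ℓ / (2|E^ℓ| − 1)),

with observed entries clamped to their observed values. The solver
iterates three steps until the mean absolute change (MAE) of the
unobserved probabilities falls below a tolerance (default 1e-5):

- **E-step** – refresh the Bernoulli posteriors p from the current degree
  estimates.
- **A-step** – exploit interlayer dependence. The aggregate topology A is
  the OR over layers; for a pair with a link witnessed in *some* observed
  layer, Bayes' rule lifts each layer's probability to
  `p^ℓ / (1 − Π_h (1 − p^h))`.
- **M-step** – re-estimate degrees, by the sparse approximation
  `d_i = Σ_j p_ij` (default) or the exact quadratic root
  `d_i = |E| − sqrt(|E|² − 2|E| s_i + s_i)`, feasible only without giant
  hubs (nodes incident to more than half a layer's edges).

Switching the A-step off yields the classic EM baseline; a uniformly
random predictor (RM) completes the comparison set. Predictions are
binarized top-k over the unobserved node pairs (k = true number of hidden
links per layer, the same oracle the random baseline receives) and scored
with the imbalance-robust Matthews correlation coefficient (MCC) and
G-mean. See `docs/methods.md` for the estimation details, parameter
defaults, and known limitations.

## Worked example

`python examples/reconstruct_partial.py` generates a two-layer multiplex
(200 nodes, Poisson(3) degrees, 70 % of each layer's edges from a shared
backbone), hides half the nodes per layer, reconstructs, and prints:

```
ground truth: 2 layers, 200 nodes, edges per layer [328, 344], interlayer edge Jaccard 0.22
EMA converged after 55 iterations (final MAE 9.6e-06)
    L1: MCC=+0.083  G-mean=0.311  TP=24 FP=220 FN=220 TN=14486
    L2: MCC=+0.075  G-mean=0.299  TP=23 FP=230 FN=230 TN=14467
   all: MCC=+0.079  G-mean=0.305  TP=47 FP=450 FN=450 TN=28953
```

A positive MCC means the predicted hidden links correlate with the true
ones over the ~15 000 unobserved pairs per layer despite the heavy
negative-class imbalance. The other examples cover layer statistics
(`layer_statistics.py`), the three-method sweep (`method_comparison.py`)
and convergence traces (`convergence_traces.py`).

## Command line

The same pipeline is available as a thin CLI:

```
emaplex simulate --nodes 200 --layers 2 --degree poisson:3 --overlap 0.7 --seed 1 --out net.edges
emaplex mask net.edges --fraction 0.5 --seed 2 --out obs.yaml
emaplex reconstruct --input net.edges --obs obs.yaml --out probabilities.tsv
emaplex evaluate --truth net.edges --obs obs.yaml --method ema
emaplex sweep --net net.edges --c 0.1:0.9:0.1 --reps 50 --out results.csv
emaplex stats net.edges
```

Networks travel as plain-text multilayer edge lists
(`layerID nodeID nodeID` records with optional `[NODES]`/`[LAYERS]`
sections); every output carries the seeds and settings that produced it.

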
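# Methods

## Problem and notation

A multiplex network Z = {Z^ℓ} consists of m layers of symmetric binary
adjacency over one shared node set N (no self-loops, no weights, no
directions; interlayer node–counterpart couplings are implicit and never
materialized). Observation is at the node level: per layer ℓ a subset
V_obs^ℓ of nodes is observed, and entry (i, j) of layer ℓ is known iff
both i and j are in V_obs^ℓ. Unknown entries are stored as a sentinel and
never read as "no link". The task is to estimate the probability of a
link at every unobserved pair.

By default each layer draws its own observed node set (the multi-source
provenance typical of real multilayer data); a shared set across layers
is available but makes every pair's observation status identical in all
layers, which empties the cross-layer evidence set and reduces the
aggregation step to a no-op.

## Estimation

The per-layer generative model is the configuration model: given degrees
d^ℓ and edge count |E^ℓ|, the prior link probability is
min(1, d_i d_j / (2|E^ℓ| − 1)). The solver alternates:

1. **E-step.** p^ℓ_ij ← prior for unobserved pairs; observed pairs stay
   clamped to their observed values at every iteration. The un-clamped
   prior matrix is kept separately for the A-step.
2. **A-step.** The aggregate topology is the OR over layers; restricted
   to observations it is ternary: 1 where some layer witnessed a link, 0
   where every layer observed absence, unknown otherwise. For an
   unobserved (i, j, ℓ) with a witnessed aggregate link, Bayes' rule
   gives p^ℓ_ij ← min(1, prior^ℓ / (1 − Π_h (1 − prior^h))), a no-op when
   the denominator vanishes. Two deliberate choices:
   - the denominator uses the *model priors*, not the observation-clamped
     posteriors — with clamped values any witnessed link makes the
     denominator exactly 1 and the update a universal no-op, destroying
     the method's advantage over plain EM;
   - the update is *evidence-gated* (applied only where the aggregate
     witnessed a link) by default, because conditioning on an aggregate
     link that no observation supports has no Bayesian justification; an
     `all_pairs` mode applies it to every unobserved pair for comparison.
   With a single layer the step is skipped unconditionally (the literal
   update would force every candidate probability to 1).
3. **M-step.** Degrees from the posteriors: the sparse-layer
   approximation d_i = Σ_j p_ij (default), or the exact stationarity root
   d_i = |E| − √(|E|² − 2|E|s_i + s_i) with s_i = Σ_j p_ij. The exact
   root exists only when no node carries more than half of the layer's
   (estimated) edge mass; an infeasible node raises a named error and
   callers may fall back to the approximation. The two updates agree to
   well under 1 % once |E| ≥ 100 s_i.

Convergence is declared when the mean absolute change of the unobserved
upper-triangular entries across all layers between consecutive iterations
drops below the tolerance (default 1e-5, cap 100 iterations;
non-convergence is flagged on the result, not raised).

### The edge count

The prior needs |E^ℓ|, which the observed data only partially determine.
Three modes are provided:

- `observed` (default): |Ê| = E_obs · C(n,2) / (# observed pairs),
  estimated once from the observed region (an unbiased density
  extrapolation under uniform node masking) and held fixed. The M-step
  then rescales the degree vector onto the model constraint
  Σ_i d_i = 2|Ê|; without that projection the degree mass of hidden
  nodes, which no observed entry anchors, decays to zero whenever the
  observed nodes carry less than the full edge mass.
- `self_consistent`: |Ê| = Σ_i d_i / 2 recomputed after every M-step.
  This makes the E/M map scale-free in the hidden-degree direction:
  hidden degrees drift toward a neutral value at a rate of only ~⟨d⟩/Σd
  per iteration, so the MAE decays as a power law and the tolerance is
  reached orders of magnitude later (on the 200-node study fixture the
  MAE is still ~9e-5 after 400 iterations). Retained as the
  assumption-free variant.
- `known`: externally supplied per-layer counts (the oracle variant used
  when ground truth is available for benchmarking).

A layer with no observed pairs (or no observed links) receives the
minimal nondegenerate mass of one edge; such a layer is unidentifiable
and its reconstruction is a flat configuration-model fixed point.

### Initialization and identifiability

Degrees start at the flat value 2|Ê|/|N| and unobserved probabilities at
U(0, 1). The flat degree start is a considered choice, not a
convenience: a node hidden in a layer contributes no observed entries
there, its degree is unidentifiable from that layer, and the update map
preserves whatever ratios the initialization assigns to hidden nodes. A
random degree start therefore bakes arbitrary seed noise permanently into
the ranking of hidden-pair probabilities; the common flat value (the
max-entropy choice for an unidentifiable parameter) leaves hidden nodes
exchangeable until cross-layer evidence separates them, and makes the
reconstruction a deterministic function of the observation. A further
practical reason: with a fixed |Ê|, any start whose total degree mass
vastly exceeds 2|Ê| puts every capped prior at 1 and freezes the
iteration at an all-ones fixed point.

A consequence worth knowing: for layers whose true degree distribution is
Poisson, node masking thins the degree into independent observed and
hidden parts, so the observed part carries *no* information about hidden
links — plain EM's degree-product ranking then performs at chance level,
and all reconstruction signal comes from the aggregation step. With
heavy-tailed degrees the observed part does inform the hidden part and
EM beats the random baseline on its own (verified in the test suite with
a truncated power-law generator).

## Evaluation

Predictions and metrics are restricted to the candidate set of each
layer: all i<j pairs not contained within that layer's observed node set
(identical to the random baseline's candidate definition; observed pairs
are never scored). Probabilities are binarized top-k with k equal to the
true number of hidden links per layer — the same oracle the random
baseline is granted, putting all three methods on equal footing — with
ties at the cutoff broken by canonical pair order; a threshold mode
(p ≥ 0.5) is also provided. Confusion counts are reported per layer and
pooled across layers. MCC uses the convention 0 when any denominator
factor vanishes; G-mean is undefined (NaN, excluded from averages) when a
class is empty. The random baseline predicts exactly k uniform candidate
pairs; its MCC is centered on zero by construction.

## Synthetic generator

The generator emulates the regimes where multiplex reconstruction is
actually attempted: sparse layers (mean degree ≈ 1.5–3, covert- and
transport-like) through denser ones (≈ 4–12, connectome-like), with a
tunable interlayer dependency — the property the aggregation step
exploits. A backbone edge set is drawn from an erased configuration model
(stub matching, self-loops and multi-edges discarded, so realized degrees
never exceed requested ones and the small degree loss is O(1/n) and
logged); each layer keeps each backbone edge independently with
probability ω and supplements its remaining degree mass with an
independent configuration-model draw. ω = 0 gives independent layers;
ω = 1 with shared degree sequences gives identical layers; realized
pairwise edge Jaccard is reported in the provenance record. Degree models:
Poisson(λ), truncated power-law (zeta weights on 1..d_max), or an
explicit sequence; an odd stub total is fixed by bumping one random node.

What the generator does **not** emulate: community structure, degree
correlations between layers beyond the shared backbone, noisy (false
positive) observations, and layer-specific node sets. Passing tests on
this generator therefore show that the machinery behaves as designed
under controlled dependency and sparsity, not that reconstruction
accuracy transfers to any particular real network.

Under the shared-backbone mechanism, each *added* layer contributes
additional correlated evidence (witness coverage of hidden links grows
with m while per-witness precision stays ≈ ω), so the EMA−EM gap grows
with the number of layers at matched per-layer density. Real multiplexes
in which extra layers are only weakly related to the existing ones show
the opposite trend (per-witness precision falls as the aggregate
accumulates irrelevant links); the generator can only produce that regime
by lowering ω for the added layers.

## Numerical choices and conventions

- Tolerance 1e-5 on the MAE of unobserved entries; iteration cap 100.
- Symmetry enforced by computing on i<j and mirroring; probabilities
  clipped to [0, 1] by the min-cap only (no other clipping is needed).
- Observed node count per layer is round-half-up of c·|N|.
- Layer statistics: density 2|E|/(|N|(|N|−1)); mean degree 2|E|/|N|;
  isolated nodes count as size-1 components so component sizes always sum
  to |N|; the coefficient of variation of component sizes uses the
  population standard deviation (0 for a single spanning component,
  well-defined for one component).
- Zero-denominator conventions: MCC → 0; A-step → no-op; G-mean → NaN.
- Seeds: every entry point takes one seed; sweeps fan out deterministic
  per-cell seeds via `numpy.random.SeedSequence`, and all methods inside
  a cell share the identical observation (paired design).
- Study problem sizes: the test suite and the acceptance script use
  200-node, 2–3-layer fixtures with Poisson(3) degrees, overlap 0.7,
  half the nodes observed, 30 paired repetitions (200 repetitions for the
  random-baseline null) — large enough for stable means, small enough to
  run in seconds.

## Known limitations

- Hidden-node degrees are unidentifiable per layer; their reconstruction
  rests entirely on cross-layer evidence. At c = 0 the output is a flat,
  unidentifiable fixed point.
- The number of nodes is assumed known; missing-node discovery is out of
  scope, as are directed, weighted, or noisily observed multiplexes.
- The `self_consistent` edge-count mode converges too slowly for routine
  use (see above); it exists for comparison with the fixed-estimate mode.
- The exact M-step can be infeasible in the presence of giant hubs; the
  error names the offending node and the approximate update remains
  available.
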
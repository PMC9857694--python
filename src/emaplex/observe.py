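"""Node-masking observation model.

Missingness is at the node level: hiding a node hides every link incident
to it, so a node pair is observed in a layer only when both endpoints are
observed there.  By default each layer draws its own observed node set
(layers of real multiplexes typically come from different sources); a
shared set across layers is available as an option.
"""

from __future__ import annotations

import math

import numpy as np

from .core import UNOBSERVED, MultiplexNetwork, PartialObservation

__all__ = ["mask_nodes", "observation_from_nodes", "unobserved_pair_mask", "n_unobserved_pairs"]


def mask_nodes(
    net: MultiplexNetwork,
    c: float,
    shared_across_layers: bool = False,
    rng_seed: int | np.random.Generator | None = None,
) -> PartialObservation:
    """Observe a uniform random fraction ``c`` of nodes per layer.

    Per layer, ``round(c * |N|)`` nodes (half-up) are drawn uniformly; with
    ``shared_across_layers`` a single draw is reused for every layer.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"observed fraction c must be in [0, 1], got {c}")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    n = net.n_nodes
    k = int(math.floor(c * n + 0.5))

    def draw() -> list[str]:
        chosen = rng.choice(n, size=k, replace=False)
        return [net.node_ids[i] for i in sorted(chosen)]

    if shared_across_layers:
        shared = draw()
        per_layer = [shared for _ in net.layer_ids]
    else:
        per_layer = [draw() for _ in net.layer_ids]
    return observation_from_nodes(net, per_layer, nominal_fraction=c)


def observation_from_nodes(
    net: MultiplexNetwork,
    observed_nodes: list[list[str]],
    nominal_fraction: float | None = None,
) -> PartialObservation:
    """Build a :class:`PartialObservation` from explicit per-layer node sets."""
    n = net.n_nodes
    index = {u: i for i, u in enumerate(net.node_ids)}
    X, masks, fracs = [], [], []
    for vobs, a in zip(observed_nodes, net.adjacency):
        obs = np.zeros(n, dtype=bool)
        obs[[index[u] for u in vobs]] = True
        mask = np.outer(obs, obs)
        np.fill_diagonal(mask, False)
        X.append(np.where(mask, a, UNOBSERVED).astype(np.int8))
        masks.append(mask)
        fracs.append(nominal_fraction if nominal_fraction is not None else obs.sum() / n)
    return PartialObservation(
        node_ids=list(net.node_ids),
        layer_ids=list(net.layer_ids),
        observed_nodes=[list(v) for v in observed_nodes],
        X=X,
        observed_pair_mask=masks,
        observed_fraction=fracs,
    )


def unobserved_pair_mask(obs: PartialObservation, layer_id: str) -> np.ndarray:
    """Strictly-upper-triangular mask of unobserved pairs of one layer.

    This is both the random model's candidate set and the evaluation
    domain: all i < j pairs not contained within the observed node set.
    """
    m = obs.observed_pair_mask[obs.layer_index(layer_id)]
    return np.triu(~m, k=1)


def n_unobserved_pairs(obs: PartialObservation, layer_id: str) -> int:
    return int(unobserved_pair_mask(obs, layer_id).sum())
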
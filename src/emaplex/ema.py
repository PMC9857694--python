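"""Expectation–maximization–aggregation (EMA) reconstruction of multiplex
networks, and its plain-EM ablation.

The generative model for each layer is the configuration model: given degree
estimates ``d`` and edge-count estimate ``|E|``, the prior link probability
between nodes i and j is ``d_i d_j / (2|E| - 1)``, capped at 1.  The solver
iterates three steps until the unobserved link probabilities stop moving:

* **E-step** — refresh the Bernoulli posterior ``p`` of every unobserved
  adjacency entry from the current degree estimates; observed entries are
  clamped to their observed values.
* **A-step** — exploit interlayer dependence: the aggregate topology A is
  the OR over layers, so a link witnessed in *some* layer is evidence for
  the same pair in every layer.  By Bayes' rule the layer posterior given
  ``A_ij = 1`` is ``p / (1 - prod_h (1 - p^h))``, applied with the
  un-clamped model priors in the denominator.
* **M-step** — re-estimate the degree sequence from the posteriors; either
  exactly via the quadratic root, or by the sparse-layer approximation
  ``d_i = sum_j p_ij`` (the default).

Convergence is the mean absolute change of the unobserved entries between
consecutive iterations falling below the tolerance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .core import PartialObservation

__all__ = [
    "EmaConfig",
    "ReconstructionState",
    "ReconstructionResult",
    "DegenerateLayerError",
    "InfeasibleDegreeError",
    "init_state",
    "e_step",
    "a_step",
    "m_step_approx",
    "m_step_exact",
    "convergence_error",
    "run_ema",
]


class DegenerateLayerError(ValueError):
    """A layer's estimated edge count makes the model prior undefined."""


class InfeasibleDegreeError(ValueError):
    """The exact degree update has no real root (giant-hub condition violated)."""

    def __init__(self, layer_id: str, node_id: str):
        self.layer_id = layer_id
        self.node_id = node_id
        super().__init__(
            f"layer {layer_id}: no real degree solution for node {node_id} "
            "(a node is incident to more than half of the layer's estimated edges)"
        )


@dataclass
class EmaConfig:
    """Solver settings.

    ``a_step_mode='off'`` yields the classic EM baseline.  In mode
    ``'evidence'`` (default) the aggregation update is applied only to pairs
    with a witnessed aggregate link (``A_ij = 1``); ``'all_pairs'`` applies
    it to every unobserved pair.  ``m_step='approx'`` uses the sparse-layer
    degree update, ``'exact'`` the quadratic root.

    ``edge_count_mode`` governs the per-layer |E| the configuration-model
    prior divides by: ``'observed'`` (default) extrapolates the observed
    region's link density once and holds it fixed; ``'self_consistent'``
    re-estimates |E| = sum_i d_i / 2 after every M-step; ``'known'`` pins it
    to externally supplied ``known_edge_counts``.  The fixed estimate keeps
    the degree iteration a contraction; the self-consistent variant leaves
    the overall degree scale a quasi-neutral direction of the update map and
    converges only slowly (it is retained as the fully assumption-free
    option).
    """

    tolerance: float = 1e-5
    max_iterations: int = 100
    m_step: str = "approx"
    a_step_mode: str = "evidence"
    edge_count_mode: str = "observed"
    rng_seed: int | None = None
    known_edge_counts: list[float] | None = None

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.m_step not in ("approx", "exact"):
            raise ValueError(f"unknown m_step {self.m_step!r}")
        if self.a_step_mode not in ("off", "evidence", "all_pairs"):
            raise ValueError(f"unknown a_step_mode {self.a_step_mode!r}")
        if self.edge_count_mode not in ("observed", "self_consistent", "known"):
            raise ValueError(f"unknown edge_count_mode {self.edge_count_mode!r}")
        if self.edge_count_mode == "known" and self.known_edge_counts is None:
            raise ValueError("edge_count_mode='known' requires known_edge_counts")


@dataclass
class ReconstructionState:
    """Mutable per-iteration state of the solver.

    ``p[l]`` holds q(Z^l_ij = 1); ``prior_p[l]`` the un-clamped,
    min-capped configuration-model probabilities from the last E-step;
    ``aggregate`` is ternary: 1 = some layer observed a link, 0 = every
    layer observed absence, -1 = unknown.
    """

    p: list[np.ndarray]
    prior_p: list[np.ndarray]
    d: list[np.ndarray]
    edge_count_est: list[float]
    aggregate: np.ndarray
    iteration: int = 0
    last_error: float = float("nan")


@dataclass
class ReconstructionResult:
    p: list[np.ndarray]
    d: list[np.ndarray]
    edge_count_est: list[float]
    iterations: int
    error_trace: list[float]
    converged: bool
    config: EmaConfig = field(repr=False, default=None)


def _aggregate_from_observations(obs: PartialObservation) -> np.ndarray:
    n = obs.n_nodes
    witnessed = np.zeros((n, n), dtype=bool)
    all_observed = np.ones((n, n), dtype=bool)
    for x, m in zip(obs.X, obs.observed_pair_mask):
        witnessed |= m & (x == 1)
        all_observed &= m
    agg = np.full((n, n), -1, dtype=np.int8)
    agg[all_observed] = 0
    agg[witnessed] = 1
    np.fill_diagonal(agg, 0)
    return agg


def _extrapolated_edge_counts(obs: PartialObservation) -> list[float]:
    """Per-layer |E| estimate from the observed region's link density.

    Under uniform node masking the observed pairs are a uniform pair sample,
    so |E| ~= E_obs * C(n,2) / (observed pairs).  A layer with no observed
    pairs (or no observed links) gets the minimal nondegenerate mass of one
    edge; such a layer is unidentifiable anyway.
    """
    n = obs.n_nodes
    total_pairs = n * (n - 1) / 2.0
    out = []
    for x, m in zip(obs.X, obs.observed_pair_mask):
        sel = np.triu(m, k=1)
        n_obs_pairs = int(sel.sum())
        e_obs = int((x[sel] == 1).sum())
        est = e_obs * total_pairs / n_obs_pairs if n_obs_pairs else 0.0
        out.append(max(est, 1.0))
    return out


def init_state(obs: PartialObservation, cfg: EmaConfig) -> ReconstructionState:
    """Initialize degrees at the neutral flat value 2|E|/|N| and unobserved
    link probabilities at U(0, 1).

    The flat degree start is deliberate: a node hidden in a layer
    contributes no observed entries there, so its degree is unidentifiable
    from that layer alone — the update map preserves whatever ratios the
    initialization assigns to hidden nodes.  A random start therefore bakes
    arbitrary seed-dependent structure into the reconstruction, while the
    common flat value (the max-entropy choice) leaves hidden nodes
    exchangeable until actual cross-layer evidence (the A-step) separates
    them.  Observed-node degrees forget the start geometrically either way.
    """
    n = obs.n_nodes
    if n < 1:
        raise ValueError("empty node set")
    rng = np.random.default_rng(cfg.rng_seed)
    if cfg.edge_count_mode == "known":
        e_est = [float(e) for e in cfg.known_edge_counts]
    elif cfg.edge_count_mode == "observed":
        e_est = _extrapolated_edge_counts(obs)
    else:
        e_est = [max(1.0, n / 2.0)] * len(obs.layer_ids)
    d, p = [], []
    for e, x, m in zip(e_est, obs.X, obs.observed_pair_mask):
        d.append(np.full(n, 2.0 * e / n))
        u = np.zeros((n, n))
        iu = np.triu_indices(n, k=1)
        u[iu] = rng.uniform(0.0, 1.0, size=len(iu[0]))
        u = u + u.T
        p.append(np.where(m, x, u).astype(float))
    return ReconstructionState(
        p=p,
        prior_p=[np.zeros((n, n)) for _ in obs.layer_ids],
        d=d,
        edge_count_est=e_est,
        aggregate=_aggregate_from_observations(obs),
    )


def e_step(state: ReconstructionState, obs: PartialObservation) -> None:
    """Configuration-model posterior refresh of p (observed entries clamped)."""
    for l, (x, m) in enumerate(zip(obs.X, obs.observed_pair_mask)):
        denom = 2.0 * state.edge_count_est[l] - 1.0
        if denom <= 0:
            raise DegenerateLayerError(
                f"layer {obs.layer_ids[l]}: estimated edge count "
                f"{state.edge_count_est[l]:.3g} leaves no model mass"
            )
        prior = np.minimum(1.0, np.outer(state.d[l], state.d[l]) / denom)
        np.fill_diagonal(prior, 0.0)
        state.prior_p[l] = prior
        state.p[l] = np.where(m, x, prior).astype(float)


def a_step(state: ReconstructionState, obs: PartialObservation, mode: str = "evidence") -> None:
    """Bayes update of unobserved entries from the aggregate topology.

    With prior probabilities ``p^h`` per layer, the probability that the
    aggregate has a link is ``1 - prod_h (1 - p^h)``; conditioning a layer
    on ``A_ij = 1`` divides its prior by that quantity.  A zero denominator
    (all priors zero) leaves the entry unchanged.  Observed entries never
    change; with a single layer the step is a no-op.
    """
    if mode == "off" or len(obs.layer_ids) < 2:
        return
    not_absent = 1.0 - np.stack(state.prior_p)  # (m, n, n)
    denom = 1.0 - np.prod(not_absent, axis=0)
    safe = denom > 0
    for l, m in enumerate(obs.observed_pair_mask):
        target = ~m & safe
        if mode == "evidence":
            target &= state.aggregate == 1
        upd = np.minimum(1.0, np.divide(state.prior_p[l], denom, out=np.zeros_like(denom), where=safe))
        state.p[l] = np.where(target, upd, state.p[l])
        np.fill_diagonal(state.p[l], 0.0)


def _project_degree_mass(state: ReconstructionState, l: int) -> None:
    """Rescale layer l's degrees onto the configuration-model constraint
    sum_i d_i = 2|E| when |E| is held fixed.

    Without this, the degree mass of hidden nodes (which no observed entry
    anchors) leaks away: the stationarity update alone drives their degrees
    to zero whenever the observed nodes carry less than the full edge mass.
    """
    total = state.d[l].sum()
    if total > 0:
        state.d[l] = state.d[l] * (2.0 * state.edge_count_est[l] / total)


def m_step_approx(
    state: ReconstructionState,
    update_edge_count: bool = True,
    project_mass: bool = False,
) -> None:
    """Sparse-layer degree update: d_i = sum_j p_ij, then |E| = sum_i d_i / 2
    (or, with ``project_mass`` under a fixed edge count, a rescaling of d
    onto sum_i d_i = 2|E|)."""
    for l in range(len(state.p)):
        state.d[l] = state.p[l].sum(axis=1)
        if update_edge_count:
            state.edge_count_est[l] = float(state.d[l].sum() / 2.0)
        elif project_mass:
            _project_degree_mass(state, l)


def m_step_exact(
    state: ReconstructionState,
    update_edge_count: bool = True,
    project_mass: bool = False,
    layer_ids: list[str] | None = None,
    node_ids: list[str] | None = None,
) -> None:
    """Exact degree update via the smaller root of the ELBO stationarity
    quadratic: d_i = |E| - sqrt(|E|^2 - 2|E| s_i + s_i) with s_i = sum_j p_ij.

    Raises :class:`InfeasibleDegreeError` when the discriminant is negative
    for some node (the no-giant-hub condition is violated); callers may fall
    back to :func:`m_step_approx`.
    """
    for l in range(len(state.p)):
        s = state.p[l].sum(axis=1)
        e = state.edge_count_est[l]
        disc = e * e - 2.0 * e * s + s
        bad = np.nonzero(disc < 0)[0]
        if bad.size:
            lid = layer_ids[l] if layer_ids else str(l)
            nid = node_ids[bad[0]] if node_ids else str(bad[0])
            raise InfeasibleDegreeError(lid, nid)
        state.d[l] = e - np.sqrt(disc)
        if update_edge_count:
            state.edge_count_est[l] = float(state.d[l].sum() / 2.0)
        elif project_mass:
            _project_degree_mass(state, l)


def convergence_error(
    p_prev: list[np.ndarray], p_curr: list[np.ndarray], obs: PartialObservation
) -> float:
    """MAE of the unobserved i<j entries between consecutive iterations.

    Returns 0 when nothing is unobserved (already converged).
    """
    total, count = 0.0, 0
    for prev, curr, m in zip(p_prev, p_curr, obs.observed_pair_mask):
        sel = np.triu(~m, k=1)
        total += np.abs(curr[sel] - prev[sel]).sum()
        count += int(sel.sum())
    return total / count if count else 0.0


def run_ema(obs: PartialObservation, cfg: EmaConfig | None = None) -> ReconstructionResult:
    """Iterate E-step, A-step, M-step until the MAE drops below tolerance.

    With ``a_step_mode='off'`` this is the classic EM baseline; with one
    layer the A-step is skipped unconditionally, so EMA and EM coincide.
    Non-convergence within ``max_iterations`` is flagged, not raised.
    """
    cfg = cfg or EmaConfig()
    state = init_state(obs, cfg)
    trace: list[float] = []
    converged = False
    for it in range(1, cfg.max_iterations + 1):
        p_prev = [p.copy() for p in state.p]
        e_step(state, obs)
        a_step(state, obs, cfg.a_step_mode)
        update_e = cfg.edge_count_mode == "self_consistent"
        if cfg.m_step == "exact":
            m_step_exact(state, update_e, not update_e, obs.layer_ids, obs.node_ids)
        else:
            m_step_approx(state, update_e, not update_e)
        err = convergence_error(p_prev, state.p, obs)
        state.iteration = it
        state.last_error = err
        trace.append(err)
        if err <= cfg.tolerance:
            converged = True
            break
    return ReconstructionResult(
        p=[p.copy() for p in state.p],
        d=[d.copy() for d in state.d],
        edge_count_est=list(state.edge_count_est),
        iterations=state.iteration,
        error_trace=trace,
        converged=converged,
        config=dataclasses.replace(cfg),
    )
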
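"""Domain types for multiplex networks, text I/O, and per-layer statistics.

A multiplex network is a set of layers over one shared node set; each layer
is an undirected, unweighted simple graph (symmetric binary adjacency, zero
diagonal).  Partial observations hide a subset of nodes per layer: a node
pair is observed in a layer only when *both* endpoints are observed there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "MultiplexNetwork",
    "PartialObservation",
    "LayerStats",
    "MultiplexFormatError",
    "read_multiplex_edgelist",
    "read_layer_files",
    "write_multiplex_edgelist",
    "check_hub_condition",
    "layer_stats",
    "layer_stats_table",
    "density",
    "mean_degree",
]

UNOBSERVED = -1  # sentinel for adjacency entries outside the observed-pair mask


class MultiplexFormatError(ValueError):
    """Malformed multilayer edge-list input."""


@dataclass
class MultiplexNetwork:
    """Complete (ground-truth or reconstructed-binary) multiplex topology.

    Parameters
    ----------
    node_ids
        Ordered unique node labels shared by all layers.
    layer_ids
        Ordered unique layer labels.
    adjacency
        One symmetric binary ``(n, n)`` matrix per layer, zero diagonal,
        indexed by the position of each node in ``node_ids``.
    """

    node_ids: list[str]
    layer_ids: list[str]
    adjacency: list[np.ndarray]

    def __post_init__(self) -> None:
        self.node_ids = [str(u) for u in self.node_ids]
        self.layer_ids = [str(l) for l in self.layer_ids]
        self.adjacency = [np.asarray(a, dtype=np.int8) for a in self.adjacency]
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_layers(self) -> int:
        return len(self.layer_ids)

    def node_index(self, label: str) -> int:
        return self.node_ids.index(label)

    def layer_index(self, layer_id: str) -> int:
        try:
            return self.layer_ids.index(str(layer_id))
        except ValueError:
            raise KeyError(f"no such layer: {layer_id!r}") from None

    def edge_count(self, layer_id: str) -> int:
        a = self.adjacency[self.layer_index(layer_id)]
        return int(a.sum()) // 2

    @property
    def edge_counts(self) -> list[int]:
        return [int(a.sum()) // 2 for a in self.adjacency]

    def edges(self, layer_id: str) -> list[tuple[str, str]]:
        """Undirected edges of one layer, endpoints in node order, i < j."""
        a = self.adjacency[self.layer_index(layer_id)]
        ii, jj = np.nonzero(np.triu(a, k=1))
        return [(self.node_ids[i], self.node_ids[j]) for i, j in zip(ii, jj)]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        n = len(self.node_ids)
        if len(set(self.node_ids)) != n:
            raise ValueError("duplicate node labels")
        if len(set(self.layer_ids)) != len(self.layer_ids):
            raise ValueError("duplicate layer ids")
        if len(self.adjacency) != len(self.layer_ids):
            raise ValueError("one adjacency matrix required per layer")
        for lid, a in zip(self.layer_ids, self.adjacency):
            if a.shape != (n, n):
                raise ValueError(f"layer {lid}: adjacency shape {a.shape} != ({n}, {n})")
            if not np.isin(a, (0, 1)).all():
                raise ValueError(f"layer {lid}: adjacency entries must be 0/1")
            if np.diagonal(a).any():
                raise ValueError(f"layer {lid}: self-loops are not allowed")
            if not np.array_equal(a, a.T):
                raise ValueError(f"layer {lid}: adjacency must be symmetric")

    @classmethod
    def from_edges(
        cls,
        layer_edges: dict[str, Iterable[tuple[str, str]]],
        node_ids: Sequence[str] | None = None,
    ) -> "MultiplexNetwork":
        """Build a network from per-layer edge lists.

        The node set is the union of all endpoints plus any extra labels in
        ``node_ids`` (which also fixes the ordering of the listed nodes).
        """
        order: dict[str, None] = {}
        for u in node_ids or ():
            order[str(u)] = None
        for edges in layer_edges.values():
            for u, v in edges:
                order[str(u)] = None
                order[str(v)] = None
        nodes = list(order)
        idx = {u: i for i, u in enumerate(nodes)}
        n = len(nodes)
        mats = []
        for lid, edges in layer_edges.items():
            a = np.zeros((n, n), dtype=np.int8)
            for u, v in edges:
                if str(u) == str(v):
                    raise ValueError(f"layer {lid}: self-loop at node {u!r}")
                i, j = idx[str(u)], idx[str(v)]
                a[i, j] = a[j, i] = 1
            mats.append(a)
        return cls(nodes, list(layer_edges), mats)


@dataclass
class PartialObservation:
    """Partially observed multiplex topology.

    ``X[l][i, j]`` equals the true adjacency wherever
    ``observed_pair_mask[l][i, j]`` is true and holds the sentinel ``-1``
    elsewhere (never to be read as "no link").  A pair is observed in layer
    ``l`` iff both endpoints belong to that layer's observed node set.
    """

    node_ids: list[str]
    layer_ids: list[str]
    observed_nodes: list[list[str]]
    X: list[np.ndarray]
    observed_pair_mask: list[np.ndarray]
    observed_fraction: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if not self.observed_fraction:
            self.observed_fraction = [len(v) / n if n else 0.0 for v in self.observed_nodes]
        self.validate()

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_layers(self) -> int:
        return len(self.layer_ids)

    def layer_index(self, layer_id: str) -> int:
        try:
            return self.layer_ids.index(str(layer_id))
        except ValueError:
            raise KeyError(f"no such layer: {layer_id!r}") from None

    def validate(self) -> None:
        n = len(self.node_ids)
        names = set(self.node_ids)
        for lid, vobs, x, m in zip(
            self.layer_ids, self.observed_nodes, self.X, self.observed_pair_mask
        ):
            unknown = set(vobs) - names
            if unknown:
                raise ValueError(f"layer {lid}: observed nodes not in node set: {sorted(unknown)}")
            if x.shape != (n, n) or m.shape != (n, n):
                raise ValueError(f"layer {lid}: shape mismatch")
            if not np.array_equal(m, m.T):
                raise ValueError(f"layer {lid}: observed-pair mask must be symmetric")
            obs = np.zeros(n, dtype=bool)
            obs[[self.node_ids.index(u) for u in vobs]] = True
            expect = np.outer(obs, obs)
            np.fill_diagonal(expect, False)
            if not np.array_equal(m, expect):
                raise ValueError(f"layer {lid}: mask inconsistent with observed node set")
            if not np.isin(x[m], (0, 1)).all():
                raise ValueError(f"layer {lid}: observed entries must be 0/1")
            if not np.array_equal(np.where(m, x, 0), np.where(m, x, 0).T):
                raise ValueError(f"layer {lid}: observed adjacency must be symmetric")


@dataclass
class LayerStats:
    """The seven per-layer descriptors used for multiplex summaries."""

    n_nodes: int
    n_edges: int
    density: float
    mean_degree: float
    mean_component_size: float
    gcc_size: int
    cov_component_size: float


# ---------------------------------------------------------------------------
# text format
# ---------------------------------------------------------------------------
# Whitespace-separated records "layerID nodeID nodeID [weight]"; '#' starts a
# comment; an optional "[NODES]" section lists node labels one per line (for
# isolated nodes and to pin the node ordering); an optional "[LAYERS]"
# section declares layer ids (needed to preserve edgeless layers);
# "[EDGES]" switches back.


def read_multiplex_edgelist(source: TextIO | str) -> MultiplexNetwork:
    """Parse a multilayer edge list into a :class:`MultiplexNetwork`.

    Duplicate records (including the symmetric duplicate) collapse to a
    single edge.  Weights, if present, must be 1.  Self-loops are rejected.
    """
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = source.read().splitlines()

    order: dict[str, None] = {}
    layer_edges: dict[str, set[tuple[str, str]]] = {}
    section = "edges"
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        upper = line.upper()
        if upper == "[NODES]":
            section = "nodes"
            continue
        if upper == "[LAYERS]":
            section = "layers"
            continue
        if upper == "[EDGES]":
            section = "edges"
            continue
        if section == "nodes":
            for tok in line.split():
                order.setdefault(tok, None)
            continue
        if section == "layers":
            for tok in line.split():
                layer_edges.setdefault(tok, set())
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise MultiplexFormatError(
                f"line {lineno}: expected 'layer node node [weight]', got {raw!r}"
            )
        lid, u, v = parts[:3]
        if len(parts) == 4:
            try:
                w = float(parts[3])
            except ValueError:
                raise MultiplexFormatError(f"line {lineno}: non-numeric weight {parts[3]!r}")
            if w != 1:
                raise MultiplexFormatError(
                    f"line {lineno}: weighted edges unsupported (weight {parts[3]})"
                )
        if u == v:
            raise MultiplexFormatError(f"line {lineno}: self-loop at node {u!r}")
        order.setdefault(u, None)
        order.setdefault(v, None)
        layer_edges.setdefault(lid, set()).add((min(u, v), max(u, v)))

    nodes = list(order)
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    mats = []
    for lid in layer_edges:
        a = np.zeros((n, n), dtype=np.int8)
        for u, v in layer_edges[lid]:
            a[idx[u], idx[v]] = a[idx[v], idx[u]] = 1
        mats.append(a)
    return MultiplexNetwork(nodes, list(layer_edges), mats)


def read_layer_files(paths: Sequence, layer_ids: Sequence[str] | None = None) -> MultiplexNetwork:
    """Read one two-column edge list per layer; layer id from the file stem."""
    import pathlib

    paths = [pathlib.Path(p) for p in paths]
    if layer_ids is None:
        layer_ids = [p.stem for p in paths]
    chunks = []
    for lid, p in zip(layer_ids, paths):
        for lineno, raw in enumerate(p.read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise MultiplexFormatError(f"{p}:{lineno}: expected 'node node [weight]'")
            chunks.append(" ".join([lid, *parts]))
    return read_multiplex_edgelist("\n".join(chunks))


def write_multiplex_edgelist(net: MultiplexNetwork, sink: TextIO) -> None:
    """Write the multilayer edge-list text format.

    Every node is listed in the ``[NODES]`` section (preserving isolated
    nodes and the node ordering), then each undirected edge once with
    endpoints in node order, so ``read(write(net))`` reproduces ``net``.
    """
    sink.write("[NODES]\n")
    for u in net.node_ids:
        sink.write(f"{u}\n")
    sink.write("[LAYERS]\n")
    for lid in net.layer_ids:
        sink.write(f"{lid}\n")
    sink.write("[EDGES]\n")
    for lid, a in zip(net.layer_ids, net.adjacency):
        ii, jj = np.nonzero(np.triu(a, k=1))
        for i, j in zip(ii, jj):
            sink.write(f"{lid} {net.node_ids[i]} {net.node_ids[j]}\n")


# ---------------------------------------------------------------------------
# validators and statistics
# ---------------------------------------------------------------------------


def check_hub_condition(net: MultiplexNetwork) -> dict[str, tuple[bool, list[str]]]:
    """Check each layer for giant hub nodes.

    The degree-based M-step has a real-valued solution only when no node is
    incident to more than half of a layer's edges, i.e. ``d_i <= |E|`` for
    every node.  Returns ``{layer_id: (ok, violating node labels)}``.
    """
    out: dict[str, tuple[bool, list[str]]] = {}
    for lid, a in zip(net.layer_ids, net.adjacency):
        e = int(a.sum()) // 2
        deg = a.sum(axis=1)
        bad = np.nonzero(deg > e)[0]
        out[lid] = (bad.size == 0, [net.node_ids[i] for i in bad])
    return out


def density(n_nodes: int, n_edges: int) -> float:
    """Link density 2|E| / (|N| (|N|-1)) of an undirected simple graph."""
    if n_nodes < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def mean_degree(n_nodes: int, n_edges: int) -> float:
    """Average degree 2|E| / |N|."""
    if n_nodes < 1:
        raise ValueError("mean degree undefined for an empty node set")
    return 2.0 * n_edges / n_nodes


def _component_sizes(a: np.ndarray) -> np.ndarray:
    n_comp, labels = connected_components(csr_matrix(a), directed=False)
    return np.bincount(labels, minlength=n_comp)


def layer_stats(net: MultiplexNetwork, layer_id: str) -> LayerStats:
    """Seven descriptors of one layer over the shared node set.

    Isolated nodes count as size-1 components, so component sizes always sum
    to |N|.  The coefficient of variation of component sizes uses the
    population standard deviation (zero when all components are equal, in
    particular for a single spanning component).
    """
    a = net.adjacency[net.layer_index(layer_id)]
    n = net.n_nodes
    e = int(a.sum()) // 2
    sizes = _component_sizes(a)
    mean_cc = float(sizes.mean())
    cov = float(sizes.std(ddof=0) / mean_cc) if mean_cc > 0 else 0.0
    return LayerStats(
        n_nodes=n,
        n_edges=e,
        density=density(n, e),
        mean_degree=mean_degree(n, e),
        mean_component_size=mean_cc,
        gcc_size=int(sizes.max()) if sizes.size else 0,
        cov_component_size=cov,
    )


def layer_stats_table(net: MultiplexNetwork):
    """All layers' statistics as a DataFrame (density scaled to x1e-3)."""
    import pandas as pd

    rows = []
    for lid in net.layer_ids:
        s = layer_stats(net, lid)
        rows.append(
            {
                "layer": lid,
                "n_nodes": s.n_nodes,
                "n_edges": s.n_edges,
                "density_x1e3": s.density * 1e3,
                "mean_degree": s.mean_degree,
                "mean_cc_size": s.mean_component_size,
                "gcc_size": s.gcc_size,
                "cov_cc_size": s.cov_component_size,
            }
        )
    return pd.DataFrame(rows)
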
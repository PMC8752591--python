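"""Attributed interaction graphs G = (u, V, E) for a particle configuration.

Two particles are connected by a (directed, both ways) edge when their
periodic distance is strictly below the interaction radius.  Node attributes
are the heading encoded as (cos theta, sin theta); the edge attribute is the
scalar periodic distance; the global input is (0, t / n_steps) — a zero
placeholder plus the normalized time of the snapshot.  The supervised target
(v_a or k at that time) is stored separately, never fed as input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vicsek import ParticleConfiguration, neighbor_pairs, periodic_displacement

__all__ = ["GraphSample", "BatchedGraphs", "configuration_to_graph", "batch_graphs"]


@dataclass
class GraphSample:
    node_attrs: np.ndarray  # (Nv, d_v)
    edge_attrs: np.ndarray  # (Ne, d_e)
    receivers: np.ndarray  # (Ne,) int
    senders: np.ndarray  # (Ne,) int
    global_attr: np.ndarray  # (d_u,)
    target: float | None = None

    @property
    def n_nodes(self) -> int:
        return self.node_attrs.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_attrs.shape[0]


@dataclass
class BatchedGraphs:
    """Several graphs packed into flat arrays with per-graph segment ids."""

    node_attrs: np.ndarray  # (sum Nv, d_v)
    edge_attrs: np.ndarray  # (sum Ne, d_e)
    receivers: np.ndarray  # (sum Ne,) into the packed node array
    senders: np.ndarray
    global_attrs: np.ndarray  # (G, d_u)
    node_graph: np.ndarray  # (sum Nv,) graph id of each node
    edge_graph: np.ndarray  # (sum Ne,) graph id of each edge
    n_graphs: int
    targets: np.ndarray | None = None  # (G,)


def configuration_to_graph(
    cfg: ParticleConfiguration,
    radius: float,
    box_side: float,
    target: float | None = None,
    time_frac: float = 0.0,
) -> GraphSample:
    """Build the interaction graph of one snapshot.

    Every neighbor pair contributes two directed edges carrying the same
    scalar distance; self-loops are excluded (the node update already passes
    a node its own attribute).
    """
    pairs = neighbor_pairs(cfg.positions, radius, box_side)
    if len(pairs):
        d = periodic_displacement(cfg.positions[pairs[:, 0]], cfg.positions[pairs[:, 1]], box_side)
        dist = np.hypot(d[:, 0], d[:, 1])
        senders = np.concatenate([pairs[:, 0], pairs[:, 1]])
        receivers = np.concatenate([pairs[:, 1], pairs[:, 0]])
        edge_attrs = np.concatenate([dist, dist])[:, None]
    else:
        senders = np.zeros(0, dtype=int)
        receivers = np.zeros(0, dtype=int)
        edge_attrs = np.zeros((0, 1))
    node_attrs = np.column_stack([np.cos(cfg.angles), np.sin(cfg.angles)])
    global_attr = np.array([0.0, float(time_frac)])
    return GraphSample(
        node_attrs=node_attrs,
        edge_attrs=edge_attrs,
        receivers=receivers,
        senders=senders,
        global_attr=global_attr,
        target=target,
    )


def batch_graphs(samples) -> BatchedGraphs:
    """Concatenate graphs; receiver/sender indices are offset per graph."""
    samples = list(samples)
    if not samples:
        raise ValueError("cannot batch zero graphs")
    node_attrs, edge_attrs, recv, send = [], [], [], []
    node_graph, edge_graph, globals_, targets = [], [], [], []
    offset = 0
    have_targets = all(s.target is not None for s in samples)
    for gid, s in enumerate(samples):
        node_attrs.append(s.node_attrs)
        edge_attrs.append(s.edge_attrs)
        recv.append(s.receivers + offset)
        send.append(s.senders + offset)
        node_graph.append(np.full(s.n_nodes, gid))
        edge_graph.append(np.full(s.n_edges, gid))
        globals_.append(s.global_attr)
        if have_targets:
            targets.append(s.target)
        offset += s.n_nodes
    return BatchedGraphs(
        node_attrs=np.concatenate(node_attrs, axis=0),
        edge_attrs=np.concatenate(edge_attrs, axis=0),
        receivers=np.concatenate(recv).astype(int),
        senders=np.concatenate(send).astype(int),
        global_attrs=np.stack(globals_, axis=0),
        node_graph=np.concatenate(node_graph).astype(int),
        edge_graph=np.concatenate(edge_graph).astype(int),
        n_graphs=len(samples),
        targets=np.asarray(targets, dtype=float) if have_targets else None,
    )
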
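"""CDGNet: encode -> recurrent graph-network block -> decode, in pure numpy.

The graph-network block applies, synchronously within each round,

    e_k' = phi_e(e_k, v_rk, v_sk, u)          per-edge update
    ebar_i' = mean of e_k' over edges with receiver i
    v_i' = phi_v(ebar_i', v_i, u)             per-node update
    ebar' = mean over all edges, vbar' = mean over all nodes
    u'   = phi_u(ebar', vbar', u)             global update

with MLP update functions and arithmetic-mean aggregations.  The block is
applied ``n_rounds`` times (default 7) with shared weights, so information
can propagate n_rounds hops across the interaction graph.  The decoder maps
the final global latent through an MLP and a logistic squash to a scalar
order-parameter prediction.

Everything runs on batched graphs (flat node/edge arrays + segment ids); a
single graph is a batch of one.  Gradients are computed by explicit
reverse-mode passes, accumulated across the shared-weight rounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .graph import BatchedGraphs, GraphSample, batch_graphs

__all__ = ["GNHyper", "CDGNet", "mlp_init", "mlp_forward", "mlp_backward"]


# ---------------------------------------------------------------------------
# parameter trees: {name: [[W, b], [W, b], ...]} — one list entry per layer

def tree_map(fn, *trees):
    t0 = trees[0]
    if isinstance(t0, dict):
        return {k: tree_map(fn, *[t[k] for t in trees]) for k in t0}
    if isinstance(t0, list):
        return [tree_map(fn, *[t[i] for t in trees]) for i in range(len(t0))]
    return fn(*trees)


def tree_leaves(tree):
    if isinstance(tree, dict):
        for k in sorted(tree):
            yield from tree_leaves(tree[k])
    elif isinstance(tree, list):
        for v in tree:
            yield from tree_leaves(v)
    else:
        yield tree


def tree_zeros_like(tree):
    return tree_map(np.zeros_like, tree)


# ---------------------------------------------------------------------------
# MLP with tanh hidden layers and a linear output layer

def mlp_init(rng: np.random.Generator, sizes) -> list:
    """Fan-in scaled Gaussian weights, zero biases."""
    layers = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        W = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, fan_out))
        layers.append([W, np.zeros(fan_out)])
    return layers


def mlp_forward(layers, x):
    """Returns (output, cache); cache holds per-layer inputs for backward."""
    cache = []
    for li, (W, b) in enumerate(layers):
        cache.append(x)
        z = x @ W + b
        x = np.tanh(z) if li < len(layers) - 1 else z
    return x, cache


def mlp_backward(layers, cache, dout):
    """Gradient of a scalar loss through the MLP; returns (dlayers, dx).

    Hidden activations are recomputed from the cached layer inputs, trading
    a little compute for not storing them in the forward pass.
    """
    dlayers = [[np.zeros_like(W), np.zeros_like(b)] for W, b in layers]
    dx = dout
    for li in range(len(layers) - 1, -1, -1):
        W, b = layers[li]
        x_in = cache[li]
        if li < len(layers) - 1:
            # recompute tanh output of this hidden layer
            a = np.tanh(x_in @ W + b)
            dz = dx * (1.0 - a * a)
        else:
            dz = dx
        dlayers[li][0] = x_in.T @ dz
        dlayers[li][1] = dz.sum(axis=0)
        dx = dz @ W.T
    return dlayers, dx


# ---------------------------------------------------------------------------
# segment helpers

def _segment_sum(x, seg, n):
    out = np.zeros((n, x.shape[1]))
    if len(seg):
        np.add.at(out, seg, x)
    return out


def _segment_mean(x, seg, n):
    counts = np.bincount(seg, minlength=n).astype(float) if len(seg) else np.zeros(n)
    return _segment_sum(x, seg, n) / np.maximum(counts, 1.0)[:, None], counts


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


# ---------------------------------------------------------------------------

@dataclass
class GNHyper:
    """Hyperparameters of a CDGNet model.

    ``mode`` selects the regression target: "va" (already in [0, 1]) or "k"
    (normalized by ``k_scale``, its sqrt(N) upper bound, during training and
    denormalized at prediction time).
    """

    mode: str = "va"
    hidden: int = 64  # latent width of node/edge/global attributes
    mlp_hidden: tuple = (64, 64)  # hidden layers of the three update MLPs
    n_rounds: int = 7
    # residual processor updates (latent + MLP output): without the skip, a
    # shared-weight tanh block iterated n_rounds times contracts node/edge
    # latents toward an input-independent fixed point and the model cannot
    # be trained; the skip preserves the update functions' inputs unchanged
    residual: bool = True
    d_v: int = 2  # (cos theta, sin theta)
    d_e: int = 1  # scalar periodic distance
    d_u: int = 2  # (0, time fraction)
    k_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("va", "k"):
            raise ValueError("mode must be 'va' or 'k'")
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        self.mlp_hidden = tuple(int(h) for h in self.mlp_hidden)


class CDGNet:
    """Encode-process-decode graph network predicting a scalar order parameter."""

    def __init__(self, hyper: GNHyper, params: dict | None = None):
        self.hyper = hyper
        if params is None:
            rng = np.random.default_rng(hyper.seed)
            h, mh = hyper.hidden, list(hyper.mlp_hidden)
            self.params = {
                "enc_v": mlp_init(rng, [hyper.d_v, h]),
                "enc_e": mlp_init(rng, [hyper.d_e, h]),
                "enc_u": mlp_init(rng, [hyper.d_u, h]),
                "phi_e": mlp_init(rng, [4 * h] + mh + [h]),
                "phi_v": mlp_init(rng, [3 * h] + mh + [h]),
                "phi_u": mlp_init(rng, [3 * h] + mh + [h]),
                "dec": mlp_init(rng, [h] + mh + [1]),
            }
        else:
            self.params = params

    # -- forward ------------------------------------------------------------

    def _as_batch(self, g):
        if isinstance(g, GraphSample):
            return batch_graphs([g])
        return g

    def forward(self, g: BatchedGraphs, params: dict | None = None):
        """Predictions (normalized scale) for a batch; returns (y, cache)."""
        p = self.params if params is None else params
        g = self._as_batch(g)
        nv, ne, ng = g.node_attrs.shape[0], g.edge_attrs.shape[0], g.n_graphs
        recv, send = g.receivers, g.senders
        v, cache_ev = mlp_forward(p["enc_v"], g.node_attrs)
        e, cache_ee = mlp_forward(p["enc_e"], g.edge_attrs)
        u, cache_eu = mlp_forward(p["enc_u"], g.global_attrs)
        rounds = []
        res = self.hyper.residual
        for _ in range(self.hyper.n_rounds):
            u_edge = u[g.edge_graph] if ne else np.zeros((0, u.shape[1]))
            edge_in = np.concatenate([e, v[recv], v[send], u_edge], axis=1)
            e_new, c_e = mlp_forward(p["phi_e"], edge_in)
            if res:
                e_new = e + e_new
            ebar_v, recv_counts = _segment_mean(e_new, recv, nv)
            node_in = np.concatenate([ebar_v, v, u[g.node_graph]], axis=1)
            v_new, c_v = mlp_forward(p["phi_v"], node_in)
            if res:
                v_new = v + v_new
            ebar_u, edge_counts = _segment_mean(e_new, g.edge_graph, ng)
            vbar_u, node_counts = _segment_mean(v_new, g.node_graph, ng)
            u_in = np.concatenate([ebar_u, vbar_u, u], axis=1)
            u_new, c_u = mlp_forward(p["phi_u"], u_in)
            if res:
                u_new = u + u_new
            rounds.append(
                dict(
                    c_e=c_e, c_v=c_v, c_u=c_u,
                    recv_counts=recv_counts, edge_counts=edge_counts,
                    node_counts=node_counts,
                )
            )
            e, v, u = e_new, v_new, u_new
        z, cache_dec = mlp_forward(p["dec"], u)
        y = _sigmoid(z[:, 0])
        cache = dict(
            graph=g, rounds=rounds, z=z, latents=(e, v, u),
            cache_ev=cache_ev, cache_ee=cache_ee, cache_eu=cache_eu,
            cache_dec=cache_dec,
        )
        return y, cache

    def predict_batch(self, g) -> np.ndarray:
        """Denormalized predictions on the target's natural scale."""
        y, _ = self.forward(g)
        return y * (self.hyper.k_scale if self.hyper.mode == "k" else 1.0)

    def predict_graph(self, sample: GraphSample) -> float:
        return float(self.predict_batch(batch_graphs([sample]))[0])

    # -- backward -----------------------------------------------------------

    def loss_and_grads(self, g: BatchedGraphs, targets: np.ndarray, params: dict | None = None):
        """Mean squared error on the normalized scale and its gradient tree."""
        p = self.params if params is None else params
        g = self._as_batch(g)
        y, cache = self.forward(g, params=p)
        t = np.asarray(targets, dtype=float)
        resid = y - t
        loss = float(np.mean(resid**2))
        # d loss / d z through the logistic squash
        dz = (2.0 / len(t)) * resid * y * (1.0 - y)
        grads = tree_zeros_like(p)
        self._backward(p, cache, dz[:, None], grads)
        return loss, grads

    def _backward(self, p, cache, dz, grads):
        g = cache["graph"]
        nv, ne, ng = g.node_attrs.shape[0], g.edge_attrs.shape[0], g.n_graphs
        recv, send = g.receivers, g.senders

        d_dec, du = mlp_backward(p["dec"], cache["cache_dec"], dz)
        _acc(grads["dec"], d_dec)
        de = np.zeros((ne, self.hyper.hidden))
        dv = np.zeros((nv, self.hyper.hidden))
        res = self.hyper.residual
        for rc in reversed(cache["rounds"]):
            # global update
            d_u_mlp, du_in = mlp_backward(p["phi_u"], rc["c_u"], du)
            _acc(grads["phi_u"], d_u_mlp)
            h = self.hyper.hidden
            debar_u = du_in[:, :h]
            dvbar_u = du_in[:, h : 2 * h]
            du_prev = du_in[:, 2 * h :].copy()
            if res:
                du_prev += du  # skip connection u' = u + phi_u(...)
            # node aggregation into the global
            ncnt = np.maximum(rc["node_counts"], 1.0)
            dv_total = dv + dvbar_u[g.node_graph] / ncnt[g.node_graph][:, None]
            # node update
            d_v_mlp, dnode_in = mlp_backward(p["phi_v"], rc["c_v"], dv_total)
            _acc(grads["phi_v"], d_v_mlp)
            debar_v = dnode_in[:, :h]
            dv_prev = dnode_in[:, h : 2 * h].copy()
            if res:
                dv_prev += dv_total
            du_prev += _segment_sum(dnode_in[:, 2 * h :], g.node_graph, ng)
            # edge aggregations (into nodes and into the global)
            rcnt = np.maximum(rc["recv_counts"], 1.0)
            ecnt = np.maximum(rc["edge_counts"], 1.0)
            de_total = de.copy()
            if ne:
                de_total += debar_v[recv] / rcnt[recv][:, None]
                de_total += debar_u[g.edge_graph] / ecnt[g.edge_graph][:, None]
            # edge update
            d_e_mlp, dedge_in = mlp_backward(p["phi_e"], rc["c_e"], de_total)
            _acc(grads["phi_e"], d_e_mlp)
            de = dedge_in[:, :h].copy()
            if res:
                de += de_total
            if ne:
                np.add.at(dv_prev, recv, dedge_in[:, h : 2 * h])
                np.add.at(dv_prev, send, dedge_in[:, 2 * h : 3 * h])
                du_prev += _segment_sum(dedge_in[:, 3 * h :], g.edge_graph, ng)
            dv, du = dv_prev, du_prev
        d_ev, _ = mlp_backward(p["enc_v"], cache["cache_ev"], dv)
        d_ee, _ = mlp_backward(p["enc_e"], cache["cache_ee"], de)
        d_eu, _ = mlp_backward(p["enc_u"], cache["cache_eu"], du)
        _acc(grads["enc_v"], d_ev)
        _acc(grads["enc_e"], d_ee)
        _acc(grads["enc_u"], d_eu)

    # -- persistence ---------------------------------------------------------

    def save(self, path):
        """Single-file checkpoint: flat weight arrays + JSON hyperparameter block."""
        flat = {}
        for name, layers in self.params.items():
            for li, (W, b) in enumerate(layers):
                flat[f"{name}.{li}.W"] = W
                flat[f"{name}.{li}.b"] = b
        meta = dict(asdict(self.hyper))
        meta["mlp_hidden"] = list(meta["mlp_hidden"])
        flat["__meta__"] = np.frombuffer(
            json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
        )
        np.savez(path, **flat)

    @classmethod
    def load(cls, path) -> "CDGNet":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"].tobytes()).decode())
            meta["mlp_hidden"] = tuple(meta["mlp_hidden"])
            hyper = GNHyper(**meta)
            params: dict = {}
            for key in data.files:
                if key == "__meta__":
                    continue
                name, li, which = key.rsplit(".", 2)
                layers = params.setdefault(name, {})
                layers.setdefault(int(li), [None, None])[0 if which == "W" else 1] = data[key]
        params = {
            name: [layers[li] for li in sorted(layers)] for name, layers in params.items()
        }
        return cls(hyper, params=params)


def _acc(into, delta):
    """Accumulate one MLP's gradient list in place."""
    for (gW, gb), (dW, db) in zip(into, delta):
        gW += dW
        gb += db
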
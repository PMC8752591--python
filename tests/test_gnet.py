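"""Graph-network core: the block schedule against a naive nested-loop
oracle, invariances, analytic gradients, and training behavior."""

import numpy as np
import pytest

from flockgn import CDGNet, GNHyper, batch_graphs, configuration_to_graph
from flockgn.gnet import mlp_forward, tree_leaves
from flockgn.graph import GraphSample
from flockgn.training import train
from flockgn.vicsek import ParticleConfiguration
from conftest import random_configuration


def random_graph(rng, nv, ne, d_v=2, d_e=1, d_u=2, target=0.5):
    if ne:
        send = rng.integers(0, nv, ne)
        recv = (send + 1 + rng.integers(0, nv - 1, ne)) % nv
    else:
        send = recv = np.zeros(0, dtype=int)
    return GraphSample(
        node_attrs=rng.normal(size=(nv, d_v)),
        edge_attrs=rng.normal(size=(ne, d_e)),
        receivers=recv,
        senders=send,
        global_attr=rng.normal(size=d_u),
        target=target,
    )


def tiny_model(n_rounds=2, hidden=4, seed=0, mode="va", k_scale=1.0):
    return CDGNet(
        GNHyper(mode=mode, hidden=hidden, mlp_hidden=(5,), n_rounds=n_rounds,
                k_scale=k_scale, seed=seed)
    )


def naive_forward(model, g):
    """Per-edge / per-node loop re-implementation of encode-process-decode.

    Evaluates the same MLPs but performs every update and mean aggregation
    with explicit Python loops, exercising the schedule, indexing, and
    aggregation independently of the vectorized implementation.
    """
    p = model.params
    v = np.array([mlp_forward(p["enc_v"], x[None, :])[0][0] for x in g.node_attrs])
    e = (
        np.array([mlp_forward(p["enc_e"], x[None, :])[0][0] for x in g.edge_attrs])
        if g.n_edges
        else np.zeros((0, model.hyper.hidden))
    )
    u = mlp_forward(p["enc_u"], g.global_attr[None, :])[0][0]
    h = model.hyper.hidden
    res = model.hyper.residual
    for _ in range(model.hyper.n_rounds):
        e_new = np.array(
            [
                (e[k] if res else 0.0)
                + mlp_forward(
                    p["phi_e"],
                    np.concatenate([e[k], v[g.receivers[k]], v[g.senders[k]], u])[None, :],
                )[0][0]
                for k in range(g.n_edges)
            ]
        ) if g.n_edges else e
        v_new = []
        for i in range(g.n_nodes):
            incoming = [e_new[k] for k in range(g.n_edges) if g.receivers[k] == i]
            ebar = np.mean(incoming, axis=0) if incoming else np.zeros(h)
            v_new.append(
                (v[i] if res else 0.0)
                + mlp_forward(p["phi_v"], np.concatenate([ebar, v[i], u])[None, :])[0][0]
            )
        v_new = np.array(v_new)
        ebar_all = e_new.mean(axis=0) if g.n_edges else np.zeros(h)
        vbar_all = v_new.mean(axis=0)
        u = (u if res else 0.0) + mlp_forward(
            p["phi_u"], np.concatenate([ebar_all, vbar_all, u])[None, :]
        )[0][0]
        e, v = e_new, v_new
    z = mlp_forward(p["dec"], u[None, :])[0][0, 0]
    return 1.0 / (1.0 + np.exp(-z))


class TestBlockCorrectness:
    @pytest.mark.parametrize("seed,nv,ne", [(0, 3, 2), (1, 5, 8), (2, 8, 14), (3, 10, 20), (4, 4, 0)])
    def test_matches_nested_loop_oracle(self, seed, nv, ne):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, nv, ne)
        model = tiny_model(n_rounds=3, seed=seed)
        y, _ = model.forward(batch_graphs([g]))
        assert abs(y[0] - naive_forward(model, g)) < 1e-10

    def test_zero_edge_graph_runs(self, rng):
        g = random_graph(rng, 5, 0)
        model = tiny_model()
        y, cache = model.forward(batch_graphs([g]))
        assert np.isfinite(y).all()
        assert cache["latents"][0].shape == (0, model.hyper.hidden)

    def test_single_round_equals_one_block(self, rng):
        # n_rounds=1 is the base case of the recurrent process
        g = random_graph(rng, 6, 9)
        m1 = tiny_model(n_rounds=1, seed=3)
        y1, _ = m1.forward(batch_graphs([g]))
        assert abs(y1[0] - naive_forward(m1, g)) < 1e-10

    def test_default_rounds_is_seven(self):
        assert GNHyper().n_rounds == 7


class TestInvariances:
    def test_permutation_invariance_of_prediction(self, rng):
        g = random_graph(rng, 12, 20)
        model = tiny_model(n_rounds=3)
        perm = rng.permutation(12)
        inv = np.argsort(perm)
        gp = GraphSample(
            g.node_attrs[perm],
            g.edge_attrs.copy(),
            inv[g.receivers],
            inv[g.senders],
            g.global_attr.copy(),
        )
        assert model.predict_graph(g) == pytest.approx(model.predict_graph(gp), rel=1e-10)

    def test_translation_invariance_of_prediction(self, rng):
        # attributes are headings and relative distances, so a rigid periodic
        # translation must leave the prediction exactly unchanged
        cfg = random_configuration(rng, 50, 6.0)
        shifted = ParticleConfiguration(np.mod(cfg.positions + [1.7, -2.3], 6.0), cfg.angles)
        model = tiny_model(n_rounds=2)
        a = model.predict_graph(configuration_to_graph(cfg, 1.0, 6.0))
        b = model.predict_graph(configuration_to_graph(shifted, 1.0, 6.0))
        assert a == pytest.approx(b, rel=1e-9)

    def test_hop_limited_propagation_without_global_pathway(self):
        # with the global-input slices of the update MLPs zeroed, influence
        # travels one edge hop per round; on a path graph a perturbation at
        # node 0 must not reach nodes beyond `n_rounds` hops
        n, rounds = 9, 3
        send = np.concatenate([np.arange(n - 1), np.arange(1, n)])
        recv = np.concatenate([np.arange(1, n), np.arange(n - 1)])
        rng = np.random.default_rng(0)
        base = GraphSample(rng.normal(size=(n, 2)), rng.normal(size=(2 * (n - 1), 1)),
                           recv, send, np.zeros(2))
        model = tiny_model(n_rounds=rounds, seed=1)
        h = model.hyper.hidden
        model.params["phi_e"][0][0][-h:, :] = 0.0  # u slice of edge MLP input
        model.params["phi_v"][0][0][-h:, :] = 0.0  # u slice of node MLP input
        _, c0 = model.forward(batch_graphs([base]))
        pert = GraphSample(base.node_attrs.copy(), base.edge_attrs, recv, send, base.global_attr)
        pert.node_attrs[0] += 1.0
        _, c1 = model.forward(batch_graphs([pert]))
        v0, v1 = c0["latents"][1], c1["latents"][1]
        changed = np.any(np.abs(v0 - v1) > 1e-12, axis=1)
        assert changed[: rounds + 1].any()
        assert not changed[rounds + 1 :].any()


class TestGradients:
    def test_analytic_matches_central_differences(self):
        rng = np.random.default_rng(0)
        graphs = [random_graph(rng, 5, 8, target=0.3), random_graph(rng, 4, 0, target=0.7)]
        batch = batch_graphs(graphs)
        model = tiny_model(n_rounds=3)
        loss, grads = model.loss_and_grads(batch, batch.targets)
        leaves_p = list(tree_leaves(model.params))
        leaves_g = list(tree_leaves(grads))
        eps = 1e-6
        check_rng = np.random.default_rng(1)
        for _ in range(50):
            li = int(check_rng.integers(len(leaves_p)))
            arr, g = leaves_p[li], leaves_g[li]
            idx = np.unravel_index(int(check_rng.integers(arr.size)), arr.shape)
            orig = arr[idx]

            def loss_at(val):
                arr[idx] = val
                y, _ = model.forward(batch)
                return float(np.mean((y - batch.targets) ** 2))

            num = (loss_at(orig + eps) - loss_at(orig - eps)) / (2 * eps)
            arr[idx] = orig
            denom = max(abs(num), abs(g[idx]), 1e-8)
            assert abs(num - g[idx]) / denom < 1e-4

    def test_batched_equals_unbatched(self, rng):
        graphs = [random_graph(rng, 6, 10), random_graph(rng, 3, 2), random_graph(rng, 5, 0)]
        model = tiny_model(n_rounds=2)
        batched = model.predict_batch(batch_graphs(graphs))
        single = np.array([model.predict_graph(g) for g in graphs])
        assert np.max(np.abs(batched - single)) < 1e-6


class TestDecodeRanges:
    def test_va_mode_in_unit_interval(self, rng):
        model = tiny_model()
        for seed in range(5):
            g = random_graph(np.random.default_rng(seed), 6, 8)
            assert 0.0 <= model.predict_graph(g) <= 1.0

    def test_k_mode_nonnegative_and_scaled(self, rng):
        model = tiny_model(mode="k", k_scale=10.0)
        g = random_graph(rng, 6, 8)
        y = model.predict_graph(g)
        assert 0.0 <= y <= 10.0

    def test_deterministic_forward(self, rng):
        g = random_graph(rng, 6, 8)
        model = tiny_model()
        assert model.predict_graph(g) == model.predict_graph(g)


class TestCheckpoint:
    def test_save_load_round_trip(self, rng, tmp_path):
        model = tiny_model(n_rounds=2, mode="k", k_scale=7.0)
        g = random_graph(rng, 6, 9)
        model.save(tmp_path / "m.npz")
        loaded = CDGNet.load(tmp_path / "m.npz")
        assert loaded.hyper == model.hyper
        assert loaded.predict_graph(g) == pytest.approx(model.predict_graph(g), rel=0, abs=0)


class TestTraining:
    def _toy_sets(self, rng, n_train=12, n_val=4):
        train_set = [random_graph(rng, 5, 6, target=0.4) for _ in range(n_train)]
        val_set = [random_graph(rng, 5, 6, target=0.4) for _ in range(n_val)]
        return train_set, val_set

    def test_constant_target_learned(self, rng):
        train_set, val_set = self._toy_sets(rng)
        model = tiny_model(n_rounds=2)
        res = train(model, train_set, val_set, epochs=60, batch_size=4, lr=3e-2,
                    optimizer="adam", seed=0, patience=None)
        assert res.best_val_loss < 1e-3

    def test_identical_seeds_identical_curves(self, rng):
        train_set, val_set = self._toy_sets(rng)
        logs = []
        for _ in range(2):
            model = tiny_model(n_rounds=2, seed=5)
            res = train(model, train_set, val_set, epochs=5, batch_size=4, lr=1e-2, seed=11)
            logs.append(res.log)
        assert logs[0].equals(logs[1])

    def test_non_finite_loss_aborts(self, rng):
        train_set, val_set = self._toy_sets(rng, 4, 2)
        model = tiny_model(n_rounds=1)
        model.params["dec"][0][0][0, 0] = np.nan
        with pytest.raises(FloatingPointError):
            train(model, train_set, val_set, epochs=2, batch_size=2, lr=1e-2, seed=0)

    def test_empty_training_set_rejected(self, rng):
        model = tiny_model()
        with pytest.raises(ValueError):
            train(model, [], [random_graph(rng, 4, 4)], epochs=1)
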
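"""Training, prediction, and evaluation for CDGNet.

Stochastic gradient descent on the mean squared error over shuffled
mini-batches, with an adaptive-moment (Adam) option; the best-validation
weights are kept.  All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gnet import CDGNet, tree_map, tree_zeros_like
from .graph import batch_graphs

__all__ = ["TrainResult", "train", "evaluate", "mean_baseline_mse", "predict_configuration"]


@dataclass
class TrainResult:
    model: CDGNet
    log: pd.DataFrame  # epoch, train_loss, val_loss
    best_epoch: int
    best_val_loss: float


def _normalized_targets(samples, hyper):
    t = np.array([s.target for s in samples], dtype=float)
    if hyper.mode == "k":
        t = t / hyper.k_scale
    return t


def mean_baseline_mse(train_targets, eval_targets) -> float:
    """MSE of always predicting the training-set mean target."""
    mu = float(np.mean(train_targets))
    return float(np.mean((np.asarray(eval_targets, dtype=float) - mu) ** 2))


def _val_loss(model, val_batch, val_targets):
    y, _ = model.forward(val_batch)
    return float(np.mean((y - val_targets) ** 2))


def train(
    model: CDGNet,
    train_samples,
    val_samples,
    *,
    epochs: int = 200,
    batch_size: int = 16,
    lr: float = 1e-3,
    optimizer: str = "sgd",
    seed: int = 0,
    patience: int | None = 30,
    verbose: bool = False,
) -> TrainResult:
    """Fit the model; returns the best-validation weights and the loss log.

    Raises ``FloatingPointError`` if the loss goes non-finite.
    """
    if not train_samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    hyper = model.hyper
    train_targets = _normalized_targets(train_samples, hyper)
    val_batch = batch_graphs(val_samples)
    val_targets = _normalized_targets(val_samples, hyper)

    state = None
    if optimizer == "adam":
        state = dict(
            m=tree_zeros_like(model.params), v=tree_zeros_like(model.params), t=0
        )
    elif optimizer != "sgd":
        raise ValueError("optimizer must be 'sgd' or 'adam'")

    best_val = _val_loss(model, val_batch, val_targets)
    best_params = tree_map(np.copy, model.params)
    best_epoch = 0
    log_rows = []
    since_best = 0
    n = len(train_samples)
    for epoch in range(1, epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            batch = batch_graphs([train_samples[i] for i in idx])
            loss, grads = model.loss_and_grads(batch, train_targets[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; lower the learning rate"
                )
            _apply_update(model.params, grads, lr, optimizer, state)
            epoch_loss += loss
            n_batches += 1
        val_loss = _val_loss(model, val_batch, val_targets)
        log_rows.append(
            dict(epoch=epoch, train_loss=epoch_loss / n_batches, val_loss=val_loss)
        )
        if verbose:
            print(f"epoch {epoch:4d}  train {epoch_loss / n_batches:.5f}  val {val_loss:.5f}")
        if val_loss < best_val:
            best_val = val_loss
            best_params = tree_map(np.copy, model.params)
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if patience is not None and since_best >= patience:
                break
    model.params = best_params
    return TrainResult(
        model=model,
        log=pd.DataFrame(log_rows),
        best_epoch=best_epoch,
        best_val_loss=best_val,
    )


def _apply_update(params, grads, lr, optimizer, state):
    if optimizer == "sgd":
        def upd(p, g):
            p -= lr * g
            return p
        tree_map(upd, params, grads)
    else:
        state["t"] += 1
        t = state["t"]
        b1, b2, eps = 0.9, 0.999, 1e-8
        def upd(p, g, m, v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**t)
            vhat = v / (1 - b2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
            return p
        tree_map(upd, params, grads, state["m"], state["v"])


def evaluate(model: CDGNet, samples, group_by=None) -> pd.DataFrame:
    """MSE / MAE of denormalized predictions, overall or per group.

    ``group_by``: optional sequence of group labels (e.g. noise values), one
    per sample.
    """
    preds = model.predict_batch(batch_graphs(samples))
    truth = np.array([s.target for s in samples], dtype=float)
    df = pd.DataFrame({"pred": preds, "truth": truth})
    df["group"] = list(group_by) if group_by is not None else "all"
    rows = []
    for g, sub in df.groupby("group"):
        err = sub["pred"] - sub["truth"]
        rows.append(
            dict(group=g, n=len(sub), mse=float(np.mean(err**2)), mae=float(np.mean(np.abs(err))))
        )
    return pd.DataFrame(rows)


def predict_configuration(
    model: CDGNet, cfg, radius: float, box_side: float, time_frac: float = 1.0
) -> float:
    """Order-parameter prediction for one particle configuration."""
    from .graph import configuration_to_graph

    g = configuration_to_graph(cfg, radius, box_side, time_frac=time_frac)
    return model.predict_graph(g)
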
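"""Shared mini-batch training loop.

Both the centralized classifier loop and each federated client's local loop
call :func:`run_epochs`, drawing the shuffle of global epoch ``t`` from a
``(seed, t)``-keyed stream. Because the shuffle schedule depends only on the
global epoch index, a single federated client training rounds x local-epochs
replays exactly the epoch sequence of a centralized run — the equivalence the
test suite checks bit-for-bit.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .engine import Adam, Module, epoch_rng

LossFn = Callable[[np.ndarray, np.ndarray], tuple[float, np.ndarray]]


def run_epochs(
    model: Module,
    opt: Adam,
    loss_fn: LossFn,
    X: np.ndarray,
    y: np.ndarray,
    *,
    epochs: int,
    batch_size: int,
    base_seed: int,
    epoch_offset: int = 0,
) -> list[float]:
    """Train for ``epochs`` epochs; returns the mean training loss per epoch.

    ``epoch_offset`` positions this call inside the global epoch schedule
    (federated round r of E local epochs passes ``r * E``).
    """
    n = X.shape[0]
    if n == 0:
        raise ValueError("training set is empty")
    losses = []
    params = model.parameters()
    for t in range(epochs):
        rng = epoch_rng(base_seed, epoch_offset + t)
        perm = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = perm[start : start + batch_size]
            out = model(X[idx])
            loss, dl = loss_fn(out, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {epoch_offset + t}, "
                    f"batch {n_batches}: training diverged"
                )
            model.backward(dl)
            opt.step(params, model.gradients())
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)
    return losses


def evaluate_loss(
    model: Module, loss_fn: LossFn, X: np.ndarray, y: np.ndarray, batch_size: int = 32
) -> float:
    """Mean loss over a dataset without updating parameters."""
    total, n = 0.0, X.shape[0]
    for start in range(0, n, batch_size):
        out = model(X[start : start + batch_size])
        loss, _ = loss_fn(out, y[start : start + batch_size])
        total += loss * min(batch_size, n - start)
    return total / n


def predict_batched(model: Module, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Forward passes in batches, concatenated."""
    outs = [model(X[s : s + batch_size]) for s in range(0, X.shape[0], batch_size)]
    return np.concatenate(outs, axis=0)
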
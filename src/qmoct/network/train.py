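"""Training loop (Adam, mean-absolute-error loss) and map prediction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from ..profiles import DispersionMap
from ..processing import FFTStack
from .model import QmRegressor

__all__ = ["TrainConfig", "Adam", "mae", "train", "predict_map"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings; the loss is fixed to mean absolute error."""

    batch_size: int = 16
    learning_rate: float = 1e-4
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


class Adam:
    """Adam optimizer over a model's parameter list."""

    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(
                p.value.dtype
            )


def mae(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute error over all elements."""
    return float(np.mean(np.abs(np.asarray(pred) - np.asarray(target))))


def _as_arrays(pairs: Iterable) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for x, y in pairs:
        xs.append(x.values if isinstance(x, FFTStack) else np.asarray(x))
        ys.append(np.asarray(getattr(y, "values", y)))
    if not xs:
        raise ValueError("empty data stream")
    x_arr = np.stack(xs).astype(np.float32)
    y_arr = np.stack(ys).astype(np.float32)
    if x_arr.ndim != 3 or y_arr.ndim != 2 or x_arr.shape[0] != y_arr.shape[0]:
        raise ValueError(
            f"stream shapes {x_arr.shape} / {y_arr.shape} are not "
            "(n, fragments, depth) / (n, depth)"
        )
    return x_arr, y_arr


def _evaluate(model: QmRegressor, x: np.ndarray, y: np.ndarray,
              batch_size: int) -> float:
    return mae(model.predict(x, batch_size=batch_size), y)


def train(
    model: QmRegressor,
    train_stream: "Callable[[int], Iterable] | Iterable",
    val_stream: "Iterable | None",
    config: TrainConfig,
) -> dict[str, list[float]]:
    """Minimise mean absolute error with Adam.

    ``train_stream`` is either a fixed iterable of (stack, profile) pairs
    or a callable ``epoch_index -> iterable`` which regenerates the data
    every epoch (the on-the-fly scheme used for synthetic training).
    Returns a history dict with per-epoch ``train_mae`` (running loss over
    the epoch's batches), ``val_mae``, and the pre-training
    ``initial_mae`` evaluated on the first epoch's data.

    With ``epochs=0`` the model is untouched and the history is empty.
    """
    history: dict[str, list[float]] = {"train_mae": [], "val_mae": [],
                                       "initial_mae": []}
    if config.epochs == 0:
        return history
    optimizer = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    val = _as_arrays(val_stream) if val_stream is not None else None
    regenerate = callable(train_stream)
    x_fixed = y_fixed = None
    if not regenerate:
        x_fixed, y_fixed = _as_arrays(train_stream)
    for epoch in range(config.epochs):
        if regenerate:
            x, y = _as_arrays(train_stream(epoch))
        else:
            x, y = x_fixed, y_fixed
        if epoch == 0:
            history["initial_mae"].append(
                _evaluate(model, x, y, config.batch_size)
            )
        order = rng.permutation(len(x))
        losses = []
        for start in range(0, len(x), config.batch_size):
            idx = order[start: start + config.batch_size]
            xb, yb = x[idx], y[idx]
            model.zero_grad()
            pred = model.forward(xb, training=True)
            losses.append(mae(pred, yb))
            grad = np.sign(pred - yb).astype(np.float32) / pred.size
            model.backward(grad)
            optimizer.step()
        history["train_mae"].append(float(np.mean(losses)))
        if val is not None:
            history["val_mae"].append(
                _evaluate(model, val[0], val[1], config.batch_size)
            )
    return history


def predict_map(model: QmRegressor, stacks) -> DispersionMap:
    """Transform FFT stacks into a dispersion map (one profile per stack)."""
    pitch = float("nan")
    if isinstance(stacks, FFTStack):
        stacks = [stacks]
    arrays = []
    for s in stacks:
        if isinstance(s, FFTStack):
            pitch = s.depth_pitch_um
            arrays.append(s.values)
        else:
            arrays.append(np.asarray(s))
    if not arrays:
        raise ValueError("no stacks to predict from")
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"stacks must share one shape, got {sorted(shapes)}")
    profiles = model.predict(np.stack(arrays).astype(np.float32))
    return DispersionMap(values=np.clip(profiles, 0.0, 1.0),
                         depth_pitch_um=pitch)
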
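"""Residual score network and the masked sequential decoder.

The network treats a (normalized) square cost matrix as a one-channel image
and learns the *residual* between the input and the assignment scores: the
output is ``Y = tanh(C - R(C))`` where ``R`` is a small stack of zero-padded
3x3 convolutions with batch normalization.  Being fully convolutional, the
same parameters apply to any matrix size.

The decoder turns a score matrix into a permutation row by row: row ``i``'s
scores over the still-unclaimed columns are softmax-normalized (claimed
columns are masked to -inf) and a column is chosen greedily or by sampling.
The accumulated log-probabilities define a proper distribution over
permutations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .layers import BatchNorm2d, Conv2d, ReLU

__all__ = [
    "PolicyModel",
    "DecodedAssignment",
    "decode",
    "decode_batch",
    "log_prob_of",
    "log_prob_grad",
    "normalize_input",
    "save_checkpoint",
    "load_checkpoint",
]

NEG_INF = -np.inf


@dataclass(frozen=True)
class DecodedAssignment:
    permutation: tuple[int, ...]
    log_probability: float
    mode: Literal["greedy", "sample"]


class PolicyModel:
    """Fully-convolutional residual score network.

    Layer stack: Conv(1->ch)+ReLU, then ``n_blocks`` of Conv(ch->ch)+BN+ReLU,
    then Conv(ch->1).  The final convolution is zero-initialized so the
    untrained network scores ``tanh(C)`` — the input matrix itself — which
    makes greedy decoding of the initial policy the plain row-greedy
    heuristic.
    """

    def __init__(
        self,
        n_blocks: int = 3,
        n_channels: int = 8,
        kernel_size: int = 3,
        seed: int = 0,
        normalization: float | None = None,
        temperature: float = 1.0,
        dtype=np.float64,
    ):
        self.n_blocks = n_blocks
        self.n_channels = n_channels
        self.kernel_size = kernel_size
        self.seed = seed
        self.normalization = None if normalization is None else float(normalization)
        self.temperature = float(temperature)
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        layers: list = [Conv2d(1, n_channels, kernel_size, rng, dtype=dtype), ReLU()]
        for _ in range(n_blocks):
            layers += [
                Conv2d(n_channels, n_channels, kernel_size, rng, dtype=dtype),
                BatchNorm2d(n_channels, dtype=dtype),
                ReLU(),
            ]
        layers.append(
            Conv2d(n_channels, 1, kernel_size, rng, zero_init=True, dtype=dtype)
        )
        self.layers = layers
        self._cache_y = None

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for idx, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                out[f"layer{idx}.{name}"] = value
        return out

    def gradients(self) -> dict[str, np.ndarray]:
        out = {}
        for idx, layer in enumerate(self.layers):
            for name, value in layer.grads.items():
                out[f"layer{idx}.{name}"] = value
        return out

    def zero_grad(self) -> None:
        for layer in self.layers:
            for g in layer.grads.values():
                g[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        state = dict(self.parameters())
        for idx, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2d):
                state[f"layer{idx}.running_mean"] = layer.running_mean
                state[f"layer{idx}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for idx, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name][...] = state[f"layer{idx}.{name}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean[...] = state[f"layer{idx}.running_mean"]
                layer.running_var[...] = state[f"layer{idx}.running_var"]

    # -- forward / backward -------------------------------------------------

    def forward(self, matrices: np.ndarray, train: bool = False) -> np.ndarray:
        """Map normalized matrices ``(B, N, N)`` or ``(N, N)`` to scores.

        Returns ``Y = tanh(input - R(input))`` with the same shape.
        """
        x = np.asarray(matrices, dtype=self.dtype)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != x.shape[2]:
            raise ValueError(f"expected square matrices, got shape {x.shape}")
        h = x[:, None]  # (B, 1, N, N)
        for layer in self.layers:
            h = layer.forward(h, train)
        residual = h[:, 0]
        y = np.tanh(x - residual)
        self._cache_y = y
        return y[0] if squeeze else y

    def backward(self, dscores: np.ndarray) -> None:
        """Accumulate parameter gradients given ``d loss / d Y``."""
        dy = np.asarray(dscores, dtype=self.dtype)
        if dy.ndim == 2:
            dy = dy[None]
        y = self._cache_y
        dpre = dy * (1.0 - y * y)  # through tanh
        dres = -dpre[:, None]      # Y depends on -R(C)
        for layer in reversed(self.layers):
            dres = layer.backward(dres)


def normalize_input(values: np.ndarray, normalization: float | None = None) -> np.ndarray:
    """Scale a raw cost matrix (or batch) into the network input range.

    ``normalization=None`` divides each matrix by its own max-abs entry, so
    inputs always land in [-1, 1] regardless of the cost scale; a positive
    float applies that fixed divisor instead.
    """
    arr = np.asarray(values, dtype=float)
    if normalization is None:
        denom = np.max(np.abs(arr), axis=(-2, -1), keepdims=True)
        return arr / np.maximum(denom, 1e-12)
    if normalization <= 0:
        raise ValueError("normalization constant must be positive")
    return arr / normalization


def _row_log_softmax(logits: np.ndarray) -> np.ndarray:
    m = logits.max()
    shifted = logits - m
    return shifted - np.log(np.exp(shifted).sum())


def decode(
    scores: np.ndarray,
    mode: Literal["greedy", "sample"] = "greedy",
    rng: np.random.Generator | int | None = None,
    temperature: float = 1.0,
) -> DecodedAssignment:
    """Decode a score matrix into a permutation with its log-probability.

    Rows are processed in ascending order; columns already claimed are masked
    out before the softmax.  ``greedy`` takes the argmax of each row's
    distribution, ``sample`` draws from it.
    """
    y = np.asarray(scores, dtype=float)
    if y.ndim != 2 or y.shape[0] != y.shape[1]:
        raise ValueError(f"expected a square score matrix, got {y.shape}")
    if mode == "sample":
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
    n = y.shape[0]
    available = np.ones(n, dtype=bool)
    perm = np.empty(n, dtype=int)
    logp = 0.0
    for i in range(n):
        logits = y[i] / temperature
        masked = np.where(available, logits, NEG_INF)
        log_probs = _row_log_softmax(masked[available])
        cols = np.flatnonzero(available)
        if mode == "greedy":
            pick = int(np.argmax(log_probs))
        elif mode == "sample":
            pick = int(rng.choice(len(cols), p=np.exp(log_probs)))
        else:
            raise ValueError(f"unknown decode mode {mode!r}")
        perm[i] = cols[pick]
        logp += float(log_probs[pick])
        available[cols[pick]] = False
    return DecodedAssignment(
        permutation=tuple(int(c) for c in perm),
        log_probability=logp,
        mode=mode,
    )


def log_prob_of(
    scores: np.ndarray, permutation, temperature: float = 1.0
) -> float:
    """Log-probability the sequential masked decoder assigns a permutation."""
    logp, _ = log_prob_grad(scores, permutation, temperature, with_grad=False)
    return logp


def log_prob_grad(
    scores: np.ndarray,
    permutation,
    temperature: float = 1.0,
    with_grad: bool = True,
) -> tuple[float, np.ndarray | None]:
    """Log-probability of a permutation and its gradient w.r.t. the scores."""
    y = np.asarray(scores, dtype=float)
    n = y.shape[0]
    perm = list(permutation)
    if sorted(perm) != list(range(n)):
        raise ValueError(f"invalid permutation for {n}x{n} scores: {perm}")
    available = np.ones(n, dtype=bool)
    logp = 0.0
    grad = np.zeros_like(y) if with_grad else None
    for i in range(n):
        cols = np.flatnonzero(available)
        log_probs = _row_log_softmax(y[i, cols] / temperature)
        pick = int(np.searchsorted(cols, perm[i]))
        if cols[pick] != perm[i]:
            raise ValueError("permutation reuses a column")
        logp += float(log_probs[pick])
        if with_grad:
            probs = np.exp(log_probs)
            g = -probs
            g[pick] += 1.0
            grad[i, cols] = g / temperature
        available[perm[i]] = False
    return logp, grad


def decode_batch(
    scores: np.ndarray,
    mode: Literal["greedy", "sample"] = "sample",
    rng: np.random.Generator | int | None = None,
    temperature: float = 1.0,
    with_grad: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Vectorized sequential decoding of a batch of score matrices.

    Returns ``(permutations (B, N), log_probs (B,), dlogp/dY or None)``;
    semantically identical to calling :func:`decode` per matrix, but rows of
    the whole batch are processed together.
    """
    y = np.asarray(scores, dtype=float)
    if y.ndim != 3 or y.shape[1] != y.shape[2]:
        raise ValueError(f"expected (B, N, N) scores, got {y.shape}")
    if mode == "sample" and not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    b, n, _ = y.shape
    available = np.ones((b, n), dtype=bool)
    perms = np.empty((b, n), dtype=int)
    logps = np.zeros(b)
    grad = np.zeros_like(y) if with_grad else None
    rows = np.arange(b)
    for i in range(n):
        logits = np.where(available, y[:, i, :] / temperature, NEG_INF)
        shifted = logits - logits.max(axis=1, keepdims=True)
        expv = np.exp(shifted)
        z = expv.sum(axis=1, keepdims=True)
        probs = expv / z
        if mode == "greedy":
            picks = np.argmax(logits, axis=1)
        else:
            cum = probs.cumsum(axis=1)
            cum /= cum[:, -1:]
            u = rng.random(b)
            picks = (u[:, None] >= cum).sum(axis=1)
            picks = np.minimum(picks, n - 1)
        perms[:, i] = picks
        logps += shifted[rows, picks] - np.log(z[:, 0])
        if with_grad:
            g = -probs
            g[rows, picks] += 1.0
            grad[:, i, :] = g / temperature
        available[rows, picks] = False
    return perms, logps, grad


# -- checkpoints ------------------------------------------------------------


def save_checkpoint(model: PolicyModel, path, extra: dict | None = None) -> None:
    """Write parameters to ``<path>.npz`` with a JSON metadata sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    meta = {
        "n_blocks": model.n_blocks,
        "n_channels": model.n_channels,
        "kernel_size": model.kernel_size,
        "seed": model.seed,
        "normalization": model.normalization,
        "temperature": model.temperature,
    }
    if extra:
        meta.update(extra)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> PolicyModel:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    model = PolicyModel(
        n_blocks=int(meta["n_blocks"]),
        n_channels=int(meta["n_channels"]),
        kernel_size=int(meta["kernel_size"]),
        seed=int(meta["seed"]),
        normalization=(None if meta.get("normalization") is None
                       else float(meta["normalization"])),
        temperature=float(meta.get("temperature", 1.0)),
    )
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict(dict(data))
    return model
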
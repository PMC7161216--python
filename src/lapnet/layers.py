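"""Minimal NumPy conv-net building blocks with explicit backward passes.

Everything here operates on arrays of shape ``(B, C, H, W)``.  Only the
pieces the score network needs are implemented: 2-D convolution with zero
padding, per-channel batch normalization without affine parameters, and
ReLU.  ``dtype`` is configurable — float32 for training throughput, float64
when gradients are checked against finite differences.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2d", "BatchNorm2d", "ReLU"]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*k*k) patch matrix for stride-1 convolution."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # windows: (B, C, H, W, k, k) -> (B, H*W, C*k*k)
    return windows.transpose(0, 2, 3, 1, 4, 5).reshape(b, h * w, c * k * k)


class Conv2d:
    """Stride-1 square convolution with zero padding preserving spatial size."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        zero_init: bool = False,
        dtype=np.float64,
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.pad = kernel_size // 2
        self.dtype = dtype
        fan_in = in_channels * kernel_size * kernel_size
        shape = (out_channels, in_channels, kernel_size, kernel_size)
        if zero_init:
            weight = np.zeros(shape, dtype=dtype)
        else:
            weight = rng.normal(0.0, np.sqrt(2.0 / fan_in), shape).astype(dtype)
        self.params = {"weight": weight, "bias": np.zeros(out_channels, dtype=dtype)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, c, h, w = x.shape
        cols = _im2col(x, self.kernel_size, self.pad)  # (B, H*W, C*k*k)
        wmat = self.params["weight"].reshape(self.out_channels, -1)
        out = cols @ wmat.T  # (B, H*W, O)
        out += self.params["bias"]
        self._cache = (cols, x.shape)
        return out.transpose(0, 2, 1).reshape(b, self.out_channels, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        b, _, h, w = x_shape
        dmat = np.ascontiguousarray(
            dout.reshape(b, self.out_channels, h * w).transpose(0, 2, 1)
        )
        self.grads["weight"] += np.tensordot(
            dmat, cols, axes=([0, 1], [0, 1])
        ).reshape(self.params["weight"].shape)
        self.grads["bias"] += dmat.sum(axis=(0, 1))
        # input gradient = convolution of dout with the flipped, transposed kernel
        flipped = self.params["weight"][:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        dcols = _im2col(dout, self.kernel_size, self.pad)
        dx = dcols @ flipped.reshape(self.in_channels, -1).T  # (B, H*W, C_in)
        return dx.transpose(0, 2, 1).reshape(x_shape)


class BatchNorm2d:
    """Per-channel normalization ``(t - E[t]) / sqrt(Var[t] + eps)``.

    Training mode normalizes with mini-batch statistics over (B, H, W) and
    updates exponential running statistics; evaluation mode uses the running
    statistics.  No learnable affine transform.
    """

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float64):
        self.eps = eps
        self.momentum = momentum
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.running_mean = np.zeros(num_channels, dtype=dtype)
        self.running_var = np.ones(num_channels, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(self.running_mean.dtype)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(self.running_var.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std.astype(x.dtype), train, x.shape)
        return xhat.astype(x.dtype)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, shape = self._cache
        if not train:
            return dout * inv_std[None, :, None, None]
        b, c, h, w = shape
        m = b * h * w
        dsum = dout.sum(axis=(0, 2, 3), keepdims=True)
        dxhat_sum = (dout * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (
            inv_std[None, :, None, None]
            * (dout - dsum / m - xhat * dxhat_sum / m)
        )


class ReLU:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask
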
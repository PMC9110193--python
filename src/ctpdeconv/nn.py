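"""Compact numpy residual CNN used as the learned plug-and-play denoiser.

Architecture (all convolutions 3x3, same padding, no normalisation):

    head: conv(1 -> n_filters), ReLU
    n_residual_blocks x [ h + convB(ReLU(convA(h))) ]
    tail: conv(n_filters -> 1)

The network predicts the NOISE RESIDUAL of its input frame (DnCNN-style),
so the denoised frame is ``x - net(x)``.  Forward and backward passes are
im2col matrix multiplications; training uses Adam on the mean-squared
error of ``(noisy - predicted residual)`` against the clean target.
Weights are float32 and serialise to a single JSON file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, UsageError

__all__ = ["ResidualCNN", "train", "TrainResult"]


def _conv2d(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """Same-padded 2D convolution. x (N,C,H,W), w (F,C,k,k) -> (N,F,H,W)."""
    N, C, H, W = x.shape
    F, _, k, _ = w.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N,C,H,W,k,k)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * k * k)
    out = cols @ w.reshape(F, -1).T + b
    return out.reshape(N, H, W, F).transpose(0, 3, 1, 2), cols


def _conv2d_backward(cols, w, dout, x_shape):
    """Gradients of _conv2d. dout (N,F,H,W) -> (dx, dw, db)."""
    N, C, H, W = x_shape
    F, _, k, _ = w.shape
    p = k // 2
    dout_flat = dout.transpose(0, 2, 3, 1).reshape(-1, F)  # (NHW, F)
    dw = (dout_flat.T @ cols).reshape(w.shape)
    db = dout_flat.sum(axis=0)
    dcols = (dout_flat @ w.reshape(F, -1)).reshape(N, H, W, C, k, k)
    dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=dout.dtype)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + H, j : j + W] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    return dxp[:, :, p : p + H, p : p + W], dw, db


@dataclass
class ResidualCNN:
    """Trainable residual CNN; see module docstring for the layout."""

    n_residual_blocks: int = 7
    n_filters: int = 15
    kernel_size: int = 3
    seed: int = 0
    params: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        if self.n_residual_blocks < 1 or self.n_filters < 1 or self.kernel_size < 1:
            raise ConfigurationError("network size parameters must be positive")
        if self.kernel_size % 2 == 0:
            raise ConfigurationError("kernel_size must be odd for same padding")
        if not self.params:
            self.params = self._init_params(np.random.default_rng(self.seed))

    def _init_params(self, rng) -> list:
        k, nf = self.kernel_size, self.n_filters

        def he(fan_out, fan_in):
            scale = np.sqrt(2.0 / (fan_in * k * k))
            w = rng.normal(0.0, scale, (fan_out, fan_in, k, k)).astype(np.float32)
            return [w, np.zeros(fan_out, dtype=np.float32)]

        params = [he(nf, 1)]
        for _ in range(self.n_residual_blocks):
            params.append(he(nf, nf))
            params.append(he(nf, nf))
        # zero-init the output conv: the untrained network predicts a zero
        # residual (identity denoiser), so training starts from the trivial
        # baseline instead of an arbitrary operator
        params.append(
            [np.zeros((1, nf, k, k), dtype=np.float32), np.zeros(1, dtype=np.float32)]
        )
        return params

    # ---- forward / backward ----------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Predict the noise residual of frames ``x`` (N,H,W) or (H,W)."""
        squeeze = x.ndim == 2
        x4 = np.ascontiguousarray(x[None] if squeeze else x, dtype=np.float32)[:, None]
        cache = {"x_shapes": [], "cols": [], "relu": [], "skips": []}
        h, cols = _conv2d(x4, *self.params[0])
        cache["x_shapes"].append(x4.shape)
        cache["cols"].append(cols)
        mask = h > 0
        h = h * mask
        cache["relu"].append(mask)
        idx = 1
        for _ in range(self.n_residual_blocks):
            skip = h
            a, cols_a = _conv2d(h, *self.params[idx])
            mask_a = a > 0
            a = a * mask_a
            b, cols_b = _conv2d(a, *self.params[idx + 1])
            cache["x_shapes"] += [skip.shape, a.shape]
            cache["cols"] += [cols_a, cols_b]
            cache["relu"].append(mask_a)
            cache["skips"].append(skip)
            h = skip + b
            idx += 2
        out, cols_out = _conv2d(h, *self.params[-1])
        cache["x_shapes"].append(h.shape)
        cache["cols"].append(cols_out)
        res = out[:, 0]
        if squeeze:
            res = res[0]
        return (res, cache) if want_cache else res

    __call__ = forward

    def backward(self, cache, dres: np.ndarray):
        """Gradients of all parameters given d(loss)/d(residual)."""
        dres4 = np.ascontiguousarray(dres, dtype=np.float32)
        if dres4.ndim == 2:
            dres4 = dres4[None]
        dres4 = dres4[:, None]
        grads = [None] * len(self.params)
        dh, dw, db = _conv2d_backward(
            cache["cols"][-1], self.params[-1][0], dres4, cache["x_shapes"][-1]
        )
        grads[-1] = [dw, db]
        idx_p = len(self.params) - 2
        idx_c = len(cache["cols"]) - 2
        for blk in range(self.n_residual_blocks - 1, -1, -1):
            # h_out = skip + convB(relu(convA(skip)))
            da, dw_b, db_b = _conv2d_backward(
                cache["cols"][idx_c], self.params[idx_p][0], dh, cache["x_shapes"][idx_c]
            )
            grads[idx_p] = [dw_b, db_b]
            da = da * cache["relu"][blk + 1]
            dskip, dw_a, db_a = _conv2d_backward(
                cache["cols"][idx_c - 1], self.params[idx_p - 1][0], da,
                cache["x_shapes"][idx_c - 1],
            )
            grads[idx_p - 1] = [dw_a, db_a]
            dh = dh + dskip
            idx_p -= 2
            idx_c -= 2
        dh = dh * cache["relu"][0]
        _, dw0, db0 = _conv2d_backward(
            cache["cols"][0], self.params[0][0], dh, cache["x_shapes"][0]
        )
        grads[0] = [dw0, db0]
        return grads

    # ---- serialization ----------------------------------------------

    def save(self, path, meta: dict | None = None) -> None:
        """Write weights plus a JSON header describing the architecture."""
        payload = {
            "spec": {
                "n_residual_blocks": self.n_residual_blocks,
                "n_filters": self.n_filters,
                "kernel_size": self.kernel_size,
            },
            "meta": meta or {},
            "params": [
                {"w": w.astype(np.float32).tolist(), "b": b.astype(np.float32).tolist()}
                for w, b in self.params
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> tuple["ResidualCNN", dict]:
        with open(path) as fh:
            payload = json.load(fh)
        spec = payload["spec"]
        params = [
            [np.asarray(p["w"], dtype=np.float32), np.asarray(p["b"], dtype=np.float32)]
            for p in payload["params"]
        ]
        net = cls(params=params, **spec)
        return net, payload.get("meta", {})


@dataclass
class TrainResult:
    net: ResidualCNN
    loss_trace: list[float]
    scale: float


def train(
    noisy: np.ndarray,
    clean: np.ndarray,
    net: ResidualCNN,
    epochs: int = 20,
    lr: float = 1e-3,
    batch_size: int = 16,
    seed: int = 0,
) -> TrainResult:
    """Adam training of the residual network on (noisy, clean) patch pairs.

    Patches are standardised by a single global scale (sd of the noisy
    set) so the loss is unit-free; the scale is returned and must be
    reapplied at inference.  The per-epoch mean loss trace is returned in
    full.  Deterministic under ``seed`` (single-threaded execution).
    """
    if len(noisy) == 0:
        raise UsageError("empty training-pair set")
    if noisy.shape != clean.shape:
        raise ConfigurationError("noisy/clean shapes differ")
    scale = float(np.std(noisy))
    if scale == 0:
        scale = 1.0
    xn = (noisy / scale).astype(np.float32)
    xc = (clean / scale).astype(np.float32)
    target = xn - xc  # the residual the net should predict

    rng = np.random.default_rng(seed)
    m = [[np.zeros_like(w), np.zeros_like(b)] for w, b in net.params]
    v = [[np.zeros_like(w), np.zeros_like(b)] for w, b in net.params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    trace: list[float] = []
    n = len(xn)
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, batch_size):
            batch = order[s : s + batch_size]
            pred, cache = net.forward(xn[batch], want_cache=True)
            err = pred - target[batch]
            losses.append(float(np.mean(err**2)))
            dres = (2.0 / err.size) * err
            grads = net.backward(cache, dres)
            step += 1
            corr1 = 1.0 - beta1**step
            corr2 = 1.0 - beta2**step
            for p, g, mp, vp in zip(net.params, grads, m, v):
                for j in range(2):
                    mp[j] = beta1 * mp[j] + (1 - beta1) * g[j]
                    vp[j] = beta2 * vp[j] + (1 - beta2) * g[j] ** 2
                    p[j] -= lr * (mp[j] / corr1) / (np.sqrt(vp[j] / corr2) + eps)
        trace.append(float(np.mean(losses)))
    return TrainResult(net=net, loss_trace=trace, scale=scale)
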
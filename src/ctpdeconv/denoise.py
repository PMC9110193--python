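"""Pluggable denoisers for the plug-and-play ADMM Z-update.

Every denoiser exposes ``residual(z)``: the estimated noise component of
``z``, so the denoised array is ``z - residual(z)``.  The solver state Z
may be a per-voxel vector (1D), a single 2D frame, a stack of frames
(N, H, W), or a full padded volume (x, y, z, t); spatial denoisers
operate on 2D (x, y) frames at each (z, t), matching how the learned
denoiser is trained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from skimage.restoration import denoise_tv_chambolle, estimate_sigma

from .errors import ConfigurationError
from .nn import ResidualCNN

__all__ = ["ZeroDenoiser", "GaussianDenoiser", "TVDenoiser", "CNNDenoiser", "as_frames"]


def as_frames(z: np.ndarray):
    """View state array as a stack of 2D spatial frames plus an inverse.

    Returns ``(frames, restore)`` where frames has shape (n, H, W) and
    ``restore(frames)`` maps back to the original layout.  1D input is
    treated as a single 1xL frame (degenerate but well-defined).
    """
    z = np.asarray(z)
    if z.ndim == 4:  # (x, y, z, t) -> (z*t, x, y)
        x, y, nz, nt = z.shape
        frames = z.transpose(2, 3, 0, 1).reshape(nz * nt, x, y)
        return frames, lambda f: f.reshape(nz, nt, x, y).transpose(2, 3, 0, 1)
    if z.ndim == 3:
        return z, lambda f: f
    if z.ndim == 2:
        return z[None], lambda f: f[0]
    if z.ndim == 1:
        return z[None, None], lambda f: f[0, 0]
    raise ConfigurationError(f"unsupported state dimensionality {z.ndim}")


@dataclass
class ZeroDenoiser:
    """Identity denoiser (zero residual); reduces PnP to plain ADMM."""

    def residual(self, z: np.ndarray) -> np.ndarray:
        return np.zeros_like(z)


@dataclass
class GaussianDenoiser:
    """Gaussian smoothing with a fixed spatial sigma (in voxels)."""

    sigma: float = 1.0

    def residual(self, z: np.ndarray) -> np.ndarray:
        frames, restore = as_frames(z)
        if frames.shape[1] == 1:  # degenerate 1D state: smooth along the vector
            smooth = gaussian_filter1d(frames.astype(float), self.sigma, axis=-1)
        else:
            smooth = gaussian_filter(frames.astype(float), (0, self.sigma, self.sigma))
        return np.asarray(z) - restore(smooth)


@dataclass
class TVDenoiser:
    """Total-variation (Chambolle) denoising of each spatial frame.

    ``weight=None`` adapts per call: the TV weight is ``weight_factor``
    times the wavelet-estimated noise sd of the frame stack, so the
    smoothing strength follows the iterate's actual noise level.
    """

    weight: float | None = None
    weight_factor: float = 1.5

    def residual(self, z: np.ndarray) -> np.ndarray:
        frames, restore = as_frames(z)
        frames = frames.astype(float)
        w = self.weight
        if w is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                sig = np.asarray(estimate_sigma(frames, channel_axis=0), dtype=float)
                sig = float(np.nanmean(sig)) if np.any(np.isfinite(sig)) else 0.0
            if not np.isfinite(sig) or sig == 0:
                return np.zeros_like(np.asarray(z), dtype=float)
            w = self.weight_factor * sig
        out = np.empty_like(frames)
        for i, fr in enumerate(frames):
            out[i] = denoise_tv_chambolle(fr, weight=w)
        return np.asarray(z) - restore(out)


@dataclass
class CNNDenoiser:
    """Learned residual CNN applied per spatial frame.

    ``scale`` standardises frames to the range the network was trained
    on; it is stored alongside the weights by :func:`ctpdeconv.deconv.train_denoiser`.
    """

    net: ResidualCNN
    scale: float = 1.0
    batch_frames: int = 16  # bounds the im2col working memory

    def residual(self, z: np.ndarray) -> np.ndarray:
        frames, restore = as_frames(z)
        x = frames.astype(np.float32) / self.scale
        pred = np.empty_like(x)
        for i in range(0, len(x), self.batch_frames):
            pred[i : i + self.batch_frames] = self.net(x[i : i + self.batch_frames])
        return restore((pred * self.scale).astype(float))

    @classmethod
    def load(cls, path) -> "CNNDenoiser":
        net, meta = ResidualCNN.load(path)
        return cls(net=net, scale=float(meta.get("scale", 1.0)))

    def save(self, path, extra_meta: dict | None = None) -> None:
        meta = {"scale": self.scale}
        meta.update(extra_meta or {})
        self.net.save(path, meta=meta)
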
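"""Indicator-dilution forward model for dynamic CT perfusion.

A tissue voxel's time-density curve (TDC, in HU above baseline) is the
convolution of the arterial input function (AIF) with the voxel's
flow-scaled residue function ``k(t) = F * R(t)``::

    TDC(t) = dt * (AIF (*) k)(t)

where ``R(t)`` is the fraction of tracer still inside the voxel ``t``
seconds after an idealised instantaneous arterial bolus, and ``F`` is the
perfusion (stored here in 1/s; see :mod:`ctpdeconv.maps` for conversion to
mL/100 g/min).  Discretised on a uniform time grid with the rectangle
rule, the convolution becomes multiplication by a block-circulant matrix
built from zero-padded AIF samples; the padding suppresses cyclic
wrap-around and makes the deconvolution delay-insensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import circulant

from .errors import ConfigurationError, DimensionError

__all__ = [
    "TimeGrid",
    "AIFCurve",
    "CTPSeries",
    "ConvOperator",
    "FlowResidueCurve",
    "FlowResidueMap",
    "estimate_baseline",
    "convolve_forward",
    "build_operator",
    "apply_adjoint",
]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform acquisition time grid.

    Parameters
    ----------
    dt
        Seconds per frame (must be positive; non-uniform sampling is
        rejected rather than resampled).
    n_frames
        Number of dynamic frames (>= 2).
    t0_index
        Index of the first post-baseline frame (bolus arrival); time-to-peak
        is reported relative to this frame.
    """

    dt: float
    n_frames: int
    t0_index: int = 0

    def __post_init__(self):
        if not self.dt > 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        if self.n_frames < 2:
            raise ConfigurationError(f"n_frames must be >= 2, got {self.n_frames}")
        if not 0 <= self.t0_index < self.n_frames:
            raise ConfigurationError(
                f"t0_index {self.t0_index} outside [0, {self.n_frames})"
            )

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.dt


@dataclass(frozen=True, eq=False)
class AIFCurve:
    """Arterial input function, in HU above baseline per frame."""

    values: np.ndarray
    grid: TimeGrid

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != self.grid.n_frames:
            raise DimensionError(
                f"AIF length {values.size} != n_frames {self.grid.n_frames}"
            )
        if not np.all(np.isfinite(values)):
            raise ConfigurationError("AIF contains non-finite values")
        if values.min() < -1e-9:
            raise ConfigurationError(
                "AIF must be non-negative after baseline subtraction"
            )


@dataclass(frozen=True, eq=False)
class CTPSeries:
    """4D CT-perfusion series (x, y, z, t) in Hounsfield units."""

    voxels: np.ndarray
    grid: TimeGrid
    voxel_size: tuple[float, float, float]
    baseline_frames: int = 4

    def __post_init__(self):
        voxels = np.asarray(self.voxels, dtype=float)
        object.__setattr__(self, "voxels", voxels)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        if voxels.ndim != 4:
            raise DimensionError(f"series must be 4D (x, y, z, t), got {voxels.ndim}D")
        if voxels.shape[-1] != self.grid.n_frames:
            raise DimensionError(
                f"time axis {voxels.shape[-1]} != n_frames {self.grid.n_frames}"
            )
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]


@dataclass(frozen=True, eq=False)
class FlowResidueCurve:
    """Flow-scaled residue k(t) = F*R(t) for one voxel, in 1/s per frame."""

    values: np.ndarray
    grid: TimeGrid

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size != self.grid.n_frames:
            raise DimensionError(
                f"residue length {values.size} != n_frames {self.grid.n_frames}"
            )
        if not np.all(np.isfinite(values)):
            raise ConfigurationError("residue curve contains non-finite values")


@dataclass(frozen=True, eq=False)
class FlowResidueMap:
    """Voxelwise flow-scaled residue, shape (x, y, z, t), in 1/s."""

    values: np.ndarray
    grid: TimeGrid

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 4 or values.shape[-1] != self.grid.n_frames:
            raise DimensionError(
                f"residue map shape {values.shape} incompatible with "
                f"n_frames {self.grid.n_frames}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape[:3]


@dataclass(frozen=True, eq=False)
class ConvOperator:
    """dt-scaled block-circulant convolution operator built from the AIF.

    ``matrix`` is a (pad_factor * n_frames)^2 circulant matrix whose first
    column holds the dt-scaled, zero-padded AIF samples.  Applied to a
    zero-padded residue it reproduces the causal discrete convolution on
    the first ``n_frames`` samples (pad_factor >= 2 suppresses wrap-around).
    """

    matrix: np.ndarray
    pad_factor: int
    dt: float
    n_frames: int

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    def apply(self, k: np.ndarray) -> np.ndarray:
        """N @ k along the last axis (k may be batched: (..., size))."""
        k = np.asarray(k)
        if k.shape[-1] != self.size:
            raise DimensionError(f"vector length {k.shape[-1]} != operator size {self.size}")
        return k @ self.matrix.T

    def pad(self, values: np.ndarray) -> np.ndarray:
        """Zero-pad curves of length n_frames to operator size (last axis)."""
        values = np.asarray(values, dtype=float)
        if values.shape[-1] != self.n_frames:
            raise DimensionError(
                f"curve length {values.shape[-1]} != n_frames {self.n_frames}"
            )
        pad = [(0, 0)] * (values.ndim - 1) + [(0, self.size - self.n_frames)]
        return np.pad(values, pad)


def estimate_baseline(series: CTPSeries) -> CTPSeries:
    """Subtract the pre-bolus baseline (mean of the first frames) per voxel.

    Converts raw HU curves into contrast enhancement; negative values may
    remain where noise dips below the baseline estimate.
    """
    nb = series.baseline_frames
    if not 1 <= nb < series.grid.n_frames:
        raise ConfigurationError(
            f"baseline_frames {nb} outside [1, {series.grid.n_frames})"
        )
    baseline = series.voxels[..., :nb].mean(axis=-1, keepdims=True)
    return replace(series, voxels=series.voxels - baseline)


def convolve_forward(aif: AIFCurve, k: FlowResidueCurve) -> np.ndarray:
    """Causal dt-scaled discrete convolution of the AIF with a residue curve.

    Returns the tissue time-density curve in HU above baseline, truncated
    to the shared grid length.
    """
    if aif.grid != k.grid:
        raise DimensionError("AIF and residue curve must share a TimeGrid")
    full = np.convolve(aif.values, k.values)
    return full[: aif.grid.n_frames] * aif.grid.dt


def build_operator(aif: AIFCurve, pad_factor: int = 2) -> ConvOperator:
    """Build the dt-scaled block-circulant operator from a (padded) AIF."""
    if pad_factor < 1:
        raise ConfigurationError(f"pad_factor must be >= 1, got {pad_factor}")
    n = aif.grid.n_frames
    if n == 0 or aif.values.size == 0:
        raise DimensionError("empty AIF")
    size = pad_factor * n
    first_col = np.zeros(size)
    first_col[:n] = aif.values
    matrix = aif.grid.dt * circulant(first_col)
    return ConvOperator(matrix=matrix, pad_factor=pad_factor, dt=aif.grid.dt, n_frames=n)


def apply_adjoint(op: ConvOperator, residual: np.ndarray) -> np.ndarray:
    """Apply the transpose operator N^T (the adjoint of the convolution)."""
    residual = np.asarray(residual)
    if residual.shape[-1] != op.size:
        raise DimensionError(
            f"vector length {residual.shape[-1]} != operator size {op.size}"
        )
    return residual @ op.matrix
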
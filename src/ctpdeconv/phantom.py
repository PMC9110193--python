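"""Digital brain-perfusion phantom.

Generates a mirror-symmetric elliptical "brain" (grey-matter ring around a
white-matter core) with an optional ischemic lesion — a concentric
core-inside-penumbra disc placed in one hemisphere — and synthesises the
4D CT-perfusion series by convolving a gamma-variate arterial bolus with
per-class flow-scaled exponential residue functions, adding a flat HU
baseline and additive Gaussian noise to emulate low-dose acquisition.

Ground truth is exported grid-consistently: the CBF map equals the class
CBF exactly (R(0)=1), while CBV/MTT are the values a perfect deconvolution
on this time grid would recover (rectangle-rule sum of the sampled
residue), so the central volume theorem cbv = cbf*mtt/60 holds exactly on
the exported maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import AIFCurve, CTPSeries, FlowResidueMap, TimeGrid, convolve_forward, FlowResidueCurve
from .errors import ConfigurationError
from .maps import CBF_SCALE, CBV_SCALE

__all__ = [
    "TissueClassSpec",
    "PhantomSpec",
    "PhantomGroundTruth",
    "gamma_variate_aif",
    "residue_exponential",
    "synthesize_phantom",
    "make_training_pairs",
    "default_tissue_classes",
]

# label volume codes: 0 background, then 1-based index into PhantomSpec.classes
BACKGROUND = 0


@dataclass(frozen=True)
class TissueClassSpec:
    """Perfusion parameters of one tissue class.

    cbf in mL/100 g/min, mtt in seconds; the implied cbv = cbf*mtt/60
    (mL/100 g) follows from the central volume theorem.
    """

    name: str
    cbf: float
    mtt: float
    lesion_role: str = "normal"  # one of {normal, core, penumbra}
    arrival_delay: float = 0.0   # bolus-arrival delay (s), collateral supply

    def __post_init__(self):
        if self.cbf < 0:
            raise ConfigurationError(f"cbf must be >= 0, got {self.cbf}")
        if not self.mtt > 0:
            raise ConfigurationError(f"mtt must be > 0, got {self.mtt}")
        if self.lesion_role not in ("normal", "core", "penumbra"):
            raise ConfigurationError(f"unknown lesion_role {self.lesion_role!r}")
        if self.arrival_delay < 0:
            raise ConfigurationError("arrival_delay must be >= 0")

    @property
    def cbv(self) -> float:
        return self.cbf * self.mtt / 60.0


def default_tissue_classes() -> tuple[TissueClassSpec, ...]:
    """Literature-standard tissue values for grey/white matter and lesion."""
    return (
        TissueClassSpec("gray_matter", cbf=60.0, mtt=4.0),
        TissueClassSpec("white_matter", cbf=25.0, mtt=5.0),
        TissueClassSpec("penumbra", cbf=20.0, mtt=10.0, lesion_role="penumbra", arrival_delay=3.0),
        TissueClassSpec("core", cbf=8.0, mtt=14.0, lesion_role="core", arrival_delay=5.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom realisation.

    The lesion is a cylinder through all slices: a core disc of
    ``core_radius`` voxels inside a penumbra disc of ``penumbra_radius``
    voxels, centred at ``lesion_center`` (in-plane voxel coordinates) in
    the right hemisphere.  ``lesion=False`` produces an exactly
    mirror-symmetric healthy brain.
    """

    shape: tuple[int, int, int] = (64, 64, 4)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 5.0)
    grid: TimeGrid = field(default_factory=lambda: TimeGrid(dt=1.0, n_frames=40, t0_index=5))
    classes: tuple[TissueClassSpec, ...] = field(default_factory=default_tissue_classes)
    aif_t0: float = 5.0
    aif_alpha: float = 3.0
    aif_beta: float = 1.5
    aif_amplitude: float = 300.0
    baseline_hu: float = 40.0
    noise_sigma: float = 5.0
    lesion: bool = True
    lesion_center: tuple[int, int] | None = None
    core_radius: float = 6.0
    penumbra_radius: float = 12.0
    brain_frac: float = 0.82   # brain ellipse semi-axes as fraction of half-extent
    wm_frac: float = 0.50      # white-matter ellipse fraction
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if self.core_radius >= self.penumbra_radius:
            raise ConfigurationError("core_radius must be smaller than penumbra_radius")
        nx = self.shape[0]
        center = self.lesion_center or (int(0.72 * nx), self.shape[1] // 2)
        object.__setattr__(self, "lesion_center", tuple(center))
        midline = (nx - 1) / 2.0
        if self.lesion and center[0] - self.penumbra_radius <= midline:
            raise ConfigurationError("lesion must lie entirely within one hemisphere")
        if self.lesion and center[0] + self.penumbra_radius >= nx:
            raise ConfigurationError("lesion larger than the hemisphere")

    @property
    def midline(self) -> float:
        """Mirror plane position along x (voxel coordinates)."""
        return (self.shape[0] - 1) / 2.0


@dataclass(frozen=True, eq=False)
class PhantomGroundTruth:
    """Per-voxel true perfusion parameters and tissue-class labels.

    cbf mL/100 g/min, cbv mL/100 g, mtt s, ttp s (relative to t0_index);
    non-brain voxels hold 0 in cbf/cbv/ttp and NaN in mtt.  ``labels`` is
    0 for background and the 1-based class index otherwise.  ``residue``
    is the noiseless flow-scaled residue map (1/s) used to generate the
    series.
    """

    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    ttp: np.ndarray
    labels: np.ndarray
    residue: FlowResidueMap

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


def gamma_variate_aif(
    t0: float, alpha: float, beta: float, amplitude: float, grid: TimeGrid
) -> AIFCurve:
    """Peak-normalised gamma-variate bolus sampled on the grid.

    value(t) = amplitude * ((t-t0)/(alpha*beta))^alpha * exp(alpha - (t-t0)/beta)
    for t > t0, zero before; the peak (= amplitude) sits at t0 + alpha*beta.
    """
    if alpha <= 0 or beta <= 0:
        raise ConfigurationError("gamma-variate shape parameters must be positive")
    if t0 < 0:
        raise ConfigurationError("bolus arrival t0 must be >= 0")
    t = grid.times
    tau = t - t0
    values = np.zeros_like(t)
    late = tau > 0
    values[late] = amplitude * (tau[late] / (alpha * beta)) ** alpha * np.exp(
        alpha - tau[late] / beta
    )
    return AIFCurve(values=values, grid=grid)


def residue_exponential(mtt: float, grid: TimeGrid) -> np.ndarray:
    """Unit exponential residue R(t) = exp(-t/mtt) sampled on the grid."""
    if mtt <= 0:
        raise ConfigurationError(f"mtt must be positive, got {mtt}")
    return np.exp(-grid.times / mtt)


def _class_label_volume(spec: PhantomSpec) -> np.ndarray:
    """Class-label volume: symmetric GM/WM anatomy, then the lesion stamp."""
    nx, ny, nz = spec.shape
    x, y = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    ax, ay = spec.brain_frac * nx / 2.0, spec.brain_frac * ny / 2.0

    names = [c.name for c in spec.classes]

    def label_of(name: str) -> int:
        return names.index(name) + 1

    plane = np.zeros((nx, ny), dtype=np.int16)
    brain = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0
    wm = ((x - cx) / (spec.wm_frac * ax)) ** 2 + ((y - cy) / (spec.wm_frac * ay)) ** 2 <= 1.0
    plane[brain] = label_of("gray_matter")
    plane[wm & brain] = label_of("white_matter")

    if spec.lesion:
        lx, ly = spec.lesion_center
        r2 = (x - lx) ** 2 + (y - ly) ** 2
        plane[(r2 <= spec.penumbra_radius**2) & brain] = label_of("penumbra")
        plane[(r2 <= spec.core_radius**2) & brain] = label_of("core")

    return np.repeat(plane[:, :, None], nz, axis=2)


def synthesize_phantom(
    spec: PhantomSpec,
) -> tuple[CTPSeries, AIFCurve, PhantomGroundTruth]:
    """Generate the noisy 4D series, its AIF and the ground truth.

    Per voxel the tissue curve is
    ``convolve_forward(aif, (cbf/6000) * exp(-t/mtt)) + baseline + N(0, sigma)``;
    identical seeds give bitwise-identical output.
    """
    grid = spec.grid
    aif = gamma_variate_aif(spec.aif_t0, spec.aif_alpha, spec.aif_beta, spec.aif_amplitude, grid)
    labels = _class_label_volume(spec)
    nx, ny, nz = spec.shape
    T = grid.n_frames

    # per-class curves (label 0 = background: zero enhancement)
    residues = np.zeros((len(spec.classes) + 1, T))
    curves = np.zeros((len(spec.classes) + 1, T))
    cbf_by_label = np.zeros(len(spec.classes) + 1)
    for i, cls in enumerate(spec.classes, start=1):
        k = (cls.cbf / CBF_SCALE) * residue_exponential(cls.mtt, grid)
        shift = int(round(cls.arrival_delay / grid.dt))
        if shift:  # delayed bolus arrival: residue support starts at the delay
            k = np.concatenate([np.zeros(shift), k[: T - shift]])
        residues[i] = k
        curves[i] = convolve_forward(aif, FlowResidueCurve(values=k, grid=grid))
        cbf_by_label[i] = cls.cbf

    clean = curves[labels]              # (x, y, z, T)
    residue_vals = residues[labels]

    rng = np.random.default_rng(spec.seed)
    noisy = clean + spec.baseline_hu + rng.normal(0.0, spec.noise_sigma, clean.shape)
    series = CTPSeries(
        voxels=noisy, grid=grid, voxel_size=spec.voxel_size,
        baseline_frames=min(4, grid.t0_index or 4),
    )

    # grid-consistent ground truth
    cbf = cbf_by_label[labels]
    cbv = CBV_SCALE * grid.dt * residue_vals.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mtt = np.where(cbf > 0, 60.0 * cbv / np.where(cbf > 0, cbf, 1.0), np.nan)
    ttp_by_label = np.zeros(len(spec.classes) + 1)
    ttp_by_label[1:] = grid.dt * (np.argmax(curves[1:], axis=-1) - grid.t0_index)
    ttp = ttp_by_label[labels]
    ttp[labels == BACKGROUND] = 0.0

    truth = PhantomGroundTruth(
        cbf=cbf, cbv=cbv, mtt=mtt, ttp=ttp, labels=labels,
        residue=FlowResidueMap(values=residue_vals, grid=grid),
    )
    return series, aif, truth


def make_training_pairs(
    spec: PhantomSpec,
    n_patches: int,
    seed: int,
    patch_size: int = 32,
    mode: str = "bsvd",
    sigma: float | None = None,
):
    """Paired (noisy, clean) 2D residue-frame patches for denoiser training.

    Clean patches are cut from ground-truth flow-scaled residue frames.
    ``mode="additive"`` corrupts them with Gaussian noise of sd ``sigma``
    (in residue units, 1/s); ``mode="bsvd"`` cuts the matching patches
    from a truncated-bSVD reconstruction of the noisy series, i.e. the
    noise the denoiser will actually see inside the unrolled solver.
    Deterministic under ``seed``.

    Returns ``(noisy, clean)`` arrays of shape (n_patches, patch, patch).
    """
    if n_patches < 1:
        raise ConfigurationError("n_patches must be >= 1")
    nx, ny, nz = spec.shape
    if patch_size > nx or patch_size > ny:
        raise ConfigurationError(
            f"patch_size {patch_size} exceeds phantom plane {nx}x{ny}"
        )
    if mode not in ("additive", "bsvd"):
        raise ConfigurationError(f"unknown training-pair mode {mode!r}")

    series, aif, truth = synthesize_phantom(spec)
    clean_map = truth.residue.values  # (x, y, z, T)

    if mode == "bsvd":
        from .core import estimate_baseline
        from .deconv import BSVDConfig, bsvd_deconvolve

        noisy_map = bsvd_deconvolve(estimate_baseline(series), aif, BSVDConfig()).values
    else:
        noisy_map = None  # per-patch additive noise below

    rng = np.random.default_rng(seed)
    T = spec.grid.n_frames
    # favour frames carrying bolus signal
    t_lo, t_hi = spec.grid.t0_index, T
    noisy = np.empty((n_patches, patch_size, patch_size))
    clean = np.empty((n_patches, patch_size, patch_size))
    if sigma is None:
        sigma = 0.2 * clean_map.max() if mode == "additive" else 0.0
    for i in range(n_patches):
        z = rng.integers(0, nz)
        t = rng.integers(t_lo, t_hi)
        x0 = rng.integers(0, nx - patch_size + 1)
        y0 = rng.integers(0, ny - patch_size + 1)
        clean[i] = clean_map[x0 : x0 + patch_size, y0 : y0 + patch_size, z, t]
        if mode == "bsvd":
            noisy[i] = noisy_map[x0 : x0 + patch_size, y0 : y0 + patch_size, z, t]
        else:
            noisy[i] = clean[i] + rng.normal(0.0, sigma, clean[i].shape)
    return noisy, clean
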
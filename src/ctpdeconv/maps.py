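"""Perfusion maps, mirror-ROI analysis and core/penumbra segmentation.

The flow-scaled residue k(t) (1/s) yields the hemodynamic parameters:

- CBF = 6000 * max_t k(t)            [mL/100 g/min]
- CBV = 100 * dt * sum_t k(t)        [mL/100 g]
- MTT = 60 * CBV / CBF               [s]  (central volume theorem)
- TTP = dt * (argmax_t TDC(t) - t0)  [s]  (from the measured series)

The constants 6000 and 100 convert the dimensionless tissue fraction per
second into clinical units assuming a tissue density of 1 g/mL; absolute
calibration (density 1.04 g/mL, hematocrit correction) can be opted in
via ``ConversionConstants``.

Lesion analysis follows clinical convention: the contralateral hemisphere
(reached by mirroring across the brain midline) is the healthy reference,
hypoperfusion is a time-to-peak delay beyond a threshold, and the infarct
core is the hypoperfused tissue whose CBF falls below a fraction of the
contralateral median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CTPSeries, FlowResidueMap
from .errors import DimensionError, UsageError

__all__ = [
    "CBF_SCALE",
    "CBV_SCALE",
    "ConversionConstants",
    "PerfusionMapSet",
    "LesionThresholds",
    "LesionSegmentation",
    "compute_maps",
    "mirror_roi",
    "segment_lesion",
    "roi_compare",
]

CBF_SCALE = 6000.0  # 1/s -> mL/100 g/min (x60 s/min, x100 g)
CBV_SCALE = 100.0   # dimensionless mL/mL -> mL/100 g


@dataclass(frozen=True)
class ConversionConstants:
    """Unit-conversion constants applied when forming the maps.

    ``tissue_density`` (g/mL) and ``hematocrit_factor`` rescale the
    relative maps to absolute units; the defaults leave maps in relative
    units (density 1, factor 1).
    """

    tissue_density: float = 1.0
    hematocrit_factor: float = 1.0

    @property
    def scale(self) -> float:
        return self.hematocrit_factor / self.tissue_density


@dataclass(frozen=True, eq=False)
class PerfusionMapSet:
    """CBF (mL/100 g/min), CBV (mL/100 g), MTT (s), TTP (s) volumes.

    MTT is NaN wherever CBF is zero; ``mtt_valid`` flags the defined
    voxels.
    """

    cbf: np.ndarray
    cbv: np.ndarray
    mtt: np.ndarray
    ttp: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        shapes = {m.shape for m in (self.cbf, self.cbv, self.mtt, self.ttp)}
        if len(shapes) != 1:
            raise DimensionError(f"perfusion maps disagree in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.cbf.shape

    @property
    def mtt_valid(self) -> np.ndarray:
        return np.isfinite(self.mtt)

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"cbf": self.cbf, "cbv": self.cbv, "mtt": self.mtt, "ttp": self.ttp}


def compute_maps(
    residue: FlowResidueMap,
    series: CTPSeries,
    conversion: ConversionConstants = ConversionConstants(),
) -> PerfusionMapSet:
    """Derive the four hemodynamic maps from a residue map and its series."""
    if residue.shape != series.shape:
        raise DimensionError(
            f"residue shape {residue.shape} != series shape {series.shape}"
        )
    dt = residue.grid.dt
    k = residue.values
    cbf = CBF_SCALE * conversion.scale * k.max(axis=-1)
    cbv = CBV_SCALE * conversion.scale * dt * k.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mtt = np.where(cbf > 0, 60.0 * cbv / np.where(cbf > 0, cbf, 1.0), np.nan)
    ttp = dt * (np.argmax(series.voxels, axis=-1) - series.grid.t0_index)
    return PerfusionMapSet(
        cbf=cbf, cbv=cbv, mtt=mtt, ttp=ttp.astype(float), voxel_size=series.voxel_size
    )


def mirror_roi(
    mask: np.ndarray, midline: float, axis: int = 0
) -> np.ndarray:
    """Reflect a boolean mask across the midline plane along ``axis``.

    The reflection of voxel index x is round(2*midline - x); reflections
    landing outside the volume are clipped away with a warning.  Applying
    the operation twice returns the original mask.
    """
    mask = np.asarray(mask, dtype=bool)
    n = mask.shape[axis]
    if not 0 <= midline <= n - 1:
        raise UsageError(f"midline {midline} outside volume extent [0, {n - 1}]")
    idx = np.rint(2.0 * midline - np.arange(n)).astype(int)
    inside = (idx >= 0) & (idx < n)
    if not inside.all() and mask.any():
        # only warn when occupied voxels are lost
        occupied = mask.sum(axis=tuple(i for i in range(mask.ndim) if i != axis))
        if occupied[~inside].any():
            warnings.warn("mirrored ROI extends outside the volume; clipped", stacklevel=2)
    out = np.zeros_like(mask)
    src = np.arange(n)[inside]
    out_idx = [slice(None)] * mask.ndim
    in_idx = [slice(None)] * mask.ndim
    out_idx[axis] = idx[inside]
    in_idx[axis] = src
    out[tuple(out_idx)] = mask[tuple(in_idx)]
    return out


@dataclass(frozen=True)
class LesionThresholds:
    """Clinical-convention segmentation thresholds.

    ``ttp_delay_s``: TTP delay vs the contralateral median that defines
    hypoperfusion (default 4 s).  ``rcbf_core``: relative CBF below which
    hypoperfused tissue is called infarct core (default 0.3 of the
    contralateral median CBF).
    """

    ttp_delay_s: float = 4.0
    rcbf_core: float = 0.3


@dataclass(frozen=True, eq=False)
class LesionSegmentation:
    """Boolean masks: hypoperfused ⊇ core, penumbra = hypoperfused \\ core."""

    hypoperfused: np.ndarray
    core: np.ndarray
    penumbra: np.ndarray
    midline_axis: int
    midline: float

    def label_volume(self) -> np.ndarray:
        """0 background, 1 penumbra, 2 core."""
        out = np.zeros(self.core.shape, dtype=np.int16)
        out[self.penumbra] = 1
        out[self.core] = 2
        return out


def segment_lesion(
    maps: PerfusionMapSet,
    thresholds: LesionThresholds = LesionThresholds(),
    brain_mask: np.ndarray | None = None,
    midline_axis: int = 0,
    midline: float | None = None,
) -> LesionSegmentation:
    """Segment infarct core and penumbra by mirror-reference thresholds.

    Each voxel is compared against the median TTP and CBF of the brain
    tissue in the opposite hemisphere: hypoperfusion is a TTP delay above
    ``ttp_delay_s``, and core additionally requires CBF below
    ``rcbf_core`` times the contralateral median CBF.
    """
    n = maps.shape[midline_axis]
    if midline is None:
        midline = (n - 1) / 2.0
    if brain_mask is None:
        brain_mask = maps.cbf > 0
    coords = np.arange(n)
    shape_axis = [1] * maps.cbf.ndim
    shape_axis[midline_axis] = n
    side = (coords < midline).reshape(shape_axis) & np.ones_like(brain_mask)

    refs = {}
    for name, this_side in (("left", side), ("right", ~side)):
        m = brain_mask & ~this_side  # contralateral tissue
        if not m.any():
            raise UsageError("no contralateral brain tissue to reference against")
        refs[name] = (np.nanmedian(maps.ttp[m]), np.nanmedian(maps.cbf[m]))

    ttp_ref = np.where(side, refs["left"][0], refs["right"][0])
    cbf_ref = np.where(side, refs["left"][1], refs["right"][1])

    hypo = brain_mask & ((maps.ttp - ttp_ref) > thresholds.ttp_delay_s)
    core = hypo & (maps.cbf < thresholds.rcbf_core * cbf_ref)
    penumbra = hypo & ~core
    return LesionSegmentation(
        hypoperfused=hypo, core=core, penumbra=penumbra,
        midline_axis=midline_axis, midline=midline,
    )


def _region_row(
    name: str, mask: np.ndarray, maps: PerfusionMapSet
) -> dict[str, float]:
    voxel_ml = float(np.prod(maps.voxel_size)) / 1000.0
    row: dict[str, float] = {
        "region": name,
        "n_voxels": int(mask.sum()),
        "volume_ml": float(mask.sum()) * voxel_ml,
    }
    for pname, vol in maps.as_dict().items():
        if mask.any():
            vals = vol[mask]
            row[f"{pname}_mean"] = float(np.nanmean(vals))
            row[f"{pname}_sd"] = float(np.nanstd(vals))
        else:
            row[f"{pname}_mean"] = np.nan
            row[f"{pname}_sd"] = np.nan
    return row


def roi_compare(maps: PerfusionMapSet, seg: LesionSegmentation) -> pd.DataFrame:
    """Mean ± sd of each perfusion parameter per lesion region and its mirror.

    Rows: core, penumbra, and their mirror-ROI references; volumes in mL.
    Empty masks produce zero-volume rows with NaN statistics.
    """
    regions = {
        "core": seg.core,
        "penumbra": seg.penumbra,
        "core_mirror": mirror_roi(seg.core, seg.midline, seg.midline_axis),
        "penumbra_mirror": mirror_roi(seg.penumbra, seg.midline, seg.midline_axis),
    }
    return pd.DataFrame([_region_row(n, m, maps) for n, m in regions.items()])
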
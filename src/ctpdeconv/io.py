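"""Reading and writing the pipeline's on-disk formats.

Volumes travel as NIfTI-1 (4D for the dynamic series, 3D per perfusion
map) with the frame interval stored in the 4th pixdim; curves as
two-column CSV (time_s, hu) or JSON; configuration and provenance as
JSON/YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import AIFCurve, CTPSeries, TimeGrid
from .errors import ConfigurationError, UsageError

__all__ = [
    "save_series",
    "load_series",
    "save_volume",
    "load_volume",
    "save_aif",
    "load_aif",
    "write_phantom_bundle",
    "load_config",
    "write_provenance",
]


def _affine(voxel_size) -> np.ndarray:
    return np.diag(list(voxel_size) + [1.0])


def save_series(series: CTPSeries, path) -> None:
    img = nib.Nifti1Image(series.voxels.astype(np.float32), _affine(series.voxel_size))
    img.header.set_zooms(tuple(series.voxel_size) + (series.grid.dt,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    sidecar = {
        "dt": series.grid.dt,
        "n_frames": series.grid.n_frames,
        "t0_index": series.grid.t0_index,
        "baseline_frames": series.baseline_frames,
        "voxel_size": list(series.voxel_size),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_series(path) -> CTPSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise UsageError(f"expected a 4D NIfTI series, got {data.ndim}D")
    sidecar_path = Path(str(path) + ".json")
    zooms = img.header.get_zooms()
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        grid = TimeGrid(meta["dt"], meta["n_frames"], meta.get("t0_index", 0))
        baseline = meta.get("baseline_frames", 4)
        voxel_size = tuple(meta.get("voxel_size", zooms[:3]))
    else:
        dt = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
        grid = TimeGrid(dt, data.shape[-1], 0)
        baseline = 4
        voxel_size = tuple(float(z) for z in zooms[:3])
    return CTPSeries(voxels=data, grid=grid, voxel_size=voxel_size, baseline_frames=baseline)


def save_volume(volume: np.ndarray, voxel_size, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32), _affine(voxel_size))
    nib.save(img, str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=float)


def save_aif(aif: AIFCurve, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "time_s": aif.grid.times.tolist(),
            "hu": aif.values.tolist(),
            "t0_index": aif.grid.t0_index,
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        pd.DataFrame({"time_s": aif.grid.times, "hu": aif.values}).to_csv(path, index=False)


def load_aif(path, t0_index: int = 0) -> AIFCurve:
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        times = np.asarray(payload["time_s"], dtype=float)
        values = np.asarray(payload["hu"], dtype=float)
        t0_index = int(payload.get("t0_index", t0_index))
    else:
        df = pd.read_csv(path)
        times = df["time_s"].to_numpy(dtype=float)
        values = df["hu"].to_numpy(dtype=float)
    if times.size < 2:
        raise UsageError("AIF needs at least two samples")
    dts = np.diff(times)
    if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        raise ConfigurationError("non-uniform AIF sampling is not supported")
    grid = TimeGrid(float(dts[0]), times.size, t0_index)
    return AIFCurve(values=values, grid=grid)


def write_phantom_bundle(outdir, series: CTPSeries, aif: AIFCurve, truth, spec) -> dict:
    """Write series, AIF, ground-truth maps and the spec sidecar; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"series": outdir / "series.nii.gz", "aif": outdir / "aif.csv"}
    save_series(series, paths["series"])
    save_aif(aif, paths["aif"])
    for name in ("cbf", "cbv", "mtt", "ttp"):
        p = outdir / f"gt_{name}.nii.gz"
        save_volume(np.nan_to_num(getattr(truth, name)), series.voxel_size, p)
        paths[f"gt_{name}"] = p
    paths["labels"] = outdir / "gt_labels.nii.gz"
    save_volume(truth.labels, series.voxel_size, paths["labels"])
    spec_dict = dataclasses.asdict(spec)
    spec_dict["grid"] = dataclasses.asdict(spec.grid)
    spec_dict["classes"] = [dataclasses.asdict(c) for c in spec.classes]
    paths["spec"] = outdir / "phantom_spec.json"
    paths["spec"].write_text(json.dumps(spec_dict, indent=2, default=str))
    return paths


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text) or {}
    return json.loads(text)


def write_provenance(path, record: dict) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
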
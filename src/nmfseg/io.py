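"""Reading and writing of NIfTI volumes, seed files and channel configs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Sequence, Tuple

import nibabel as nib
import numpy as np
import yaml

from .features import MPMRIStudy
from .initialization import SeedSet
from .preprocess import DSCSeries, DWISeries


def read_volume(path) -> Tuple[np.ndarray, Tuple[float, float, float]]:
    """Load a 3D/4D NIfTI volume and its voxel spacing (mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing


def write_volume(path, data: np.ndarray, spacing: Sequence[float]) -> None:
    affine = np.diag(list(spacing[:3]) + [1.0])
    dtype = np.uint8 if data.dtype == bool else np.float32
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=dtype), affine), str(path))


def load_seeds(path) -> SeedSet:
    """Seed file: JSON list of ``{"x":, "y":, "z":, "label":}`` entries
    in 0-based voxel coordinates of the NIfTI grid."""
    entries = json.loads(Path(path).read_text())
    return SeedSet(
        seeds=[((int(e["x"]), int(e["y"]), int(e["z"])), e["label"]) for e in entries]
    )


def save_seeds(path, seeds: SeedSet) -> None:
    payload = [
        {"x": int(c[0]), "y": int(c[1]), "z": int(c[2]), "label": lb}
        for c, lb in seeds.seeds
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_study(config_path) -> MPMRIStudy:
    """Assemble a study from a YAML config.

    Expected keys: ``channels`` (name -> NIfTI path), ``mask`` (path),
    optional ``slice_range`` ([start, stop]).  Relative paths resolve
    against the config file's directory.
    """
    cfg_path = Path(config_path)
    cfg = yaml.safe_load(cfg_path.read_text())
    base = cfg_path.parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    channels: Dict[str, np.ndarray] = {}
    spacing = None
    for name, p in cfg["channels"].items():
        vol, sp = read_volume(resolve(p))
        channels[name] = vol
        spacing = spacing or sp
    mask, _ = read_volume(resolve(cfg["mask"]))
    slice_range = tuple(cfg["slice_range"]) if "slice_range" in cfg else None
    return MPMRIStudy(
        channels=channels, spacing=spacing, brain_mask=mask > 0, slice_range=slice_range
    )


def load_dwi(path, sidecar_path) -> DWISeries:
    """4D DWI NIfTI plus a JSON sidecar with ``bvalues``."""
    data, spacing = read_volume(path)
    meta = json.loads(Path(sidecar_path).read_text())
    return DWISeries(volumes=data, bvalues=meta["bvalues"], spacing=spacing)


def load_dsc(path, sidecar_path) -> DSCSeries:
    """4D DSC NIfTI plus a JSON sidecar with ``n_baseline``/``echo_time_ms``."""
    data, _ = read_volume(path)
    meta = json.loads(Path(sidecar_path).read_text())
    return DSCSeries(
        volumes=data, n_baseline=int(meta["n_baseline"]),
        echo_time=float(meta["echo_time_ms"]),
    )
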
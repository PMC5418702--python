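"""Feature-matrix assembly from co-registered MRI channel volumes.

Each analysed voxel becomes one column of a non-negative matrix ``X``.
Rows are the channel intensities rescaled to [0, 1], followed by 3x3 and
5x5 in-plane neighbourhood means of every channel, so six channels yield
18 rows.  Volumes are indexed ``(x, y, z)`` with the axial plane spanned
by the first two axes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

#: channels dropped in conventional-MRI-only mode (b0 is kept as a
#: T2-weighted surrogate)
CMRI_EXCLUDED = ("rCBV", "ADC")


@dataclass
class MPMRIStudy:
    """A co-registered multi-parametric MRI study.

    Parameters
    ----------
    channels : dict of str -> ndarray
        Named 3D volumes, all on the same grid.
    spacing : tuple of float
        Voxel size ``(dx, dy, dz)`` in mm.
    brain_mask : ndarray of bool
        Brain mask on the same grid.
    slice_range : tuple of int
        Half-open ``(start, stop)`` range of axial (z) slices to analyse.
    """

    channels: Dict[str, np.ndarray]
    spacing: Tuple[float, float, float]
    brain_mask: np.ndarray
    slice_range: Tuple[int, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels must share one grid, got shapes {shapes}")
        (shape,) = shapes
        if self.brain_mask.shape != shape:
            raise ValueError("brain_mask grid differs from channel grid")
        self.brain_mask = self.brain_mask.astype(bool)
        if self.slice_range is None:
            self.slice_range = (0, shape[2])
        lo, hi = self.slice_range
        if not (0 <= lo < hi <= shape[2]):
            raise ValueError(f"invalid slice_range {self.slice_range} for nz={shape[2]}")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.brain_mask.shape

    def analysis_mask(self) -> np.ndarray:
        """Brain mask restricted to the analysed slice range."""
        m = np.zeros_like(self.brain_mask)
        lo, hi = self.slice_range
        m[:, :, lo:hi] = self.brain_mask[:, :, lo:hi]
        return m


@dataclass
class FeatureMatrix:
    """The ``m x n`` non-negative input matrix with its voxel bookkeeping.

    ``voxel_index[j]`` holds the ``(x, y, z)`` grid coordinate of column
    ``j``; columns enumerate in-mask voxels of the analysed slices in
    ``(z, y, x)`` raster order (z slowest).
    """

    X: np.ndarray
    feature_names: List[str]
    voxel_index: np.ndarray  # (n, 3) int
    spacing: Tuple[float, float, float]
    shape: Tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.feature_names):
            raise ValueError("feature_names length must match row count")
        if self.X.shape[1] != self.voxel_index.shape[0]:
            raise ValueError("voxel_index length must match column count")

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    def column_lookup(self) -> Dict[Tuple[int, int, int], int]:
        """Map (x, y, z) -> column index."""
        return {tuple(c): j for j, c in enumerate(map(tuple, self.voxel_index))}

    def map_to_volume(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-column vector back into image space."""
        vol = np.full(self.shape, fill, dtype=float)
        vol[self.voxel_index[:, 0], self.voxel_index[:, 1], self.voxel_index[:, 2]] = values
        return vol


def rescale_features(study: MPMRIStudy) -> MPMRIStudy:
    """Linearly rescale each channel's full range to [0, 1].

    The min/max statistics are computed over in-mask voxels of the
    analysed slices only; a constant channel maps to all zeros (with a
    warning).  Out-of-mask voxels are set to 0.
    """
    mask = study.analysis_mask()
    if not mask.any():
        raise ValueError("empty analysis mask: nothing to rescale")
    rescaled: Dict[str, np.ndarray] = {}
    for name, vol in study.channels.items():
        if not np.all(np.isfinite(vol[mask])):
            raise ValueError(f"channel {name!r} has non-finite in-mask values")
        lo = float(vol[mask].min())
        hi = float(vol[mask].max())
        out = np.zeros_like(vol, dtype=float)
        if hi == lo:
            warnings.warn(f"channel {name!r} is constant over the mask; rescaled to zeros")
        else:
            out[mask] = (vol[mask] - lo) / (hi - lo)
        rescaled[name] = out
    return replace(study, channels=rescaled)


def neighborhood_average(channel: np.ndarray, mask: np.ndarray, k: int) -> np.ndarray:
    """Mask-aware ``k x k`` in-plane mean assigned to the central voxel.

    Out-of-mask and out-of-bounds neighbours are excluded from the mean
    (the window sum is renormalised by the in-mask neighbour count), so
    averaging cannot leak background zeros into the brain.
    """
    if k not in (3, 5):
        raise ValueError(f"window size must be 3 or 5, got {k}")
    m = mask.astype(float)
    size = (k, k, 1)  # in-plane only; adjacent slices are not mixed
    num = ndimage.uniform_filter(channel * m, size=size, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(m, size=size, mode="constant", cval=0.0)
    out = np.zeros_like(channel, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    out[~mask.astype(bool)] = 0.0
    return out


def _raster_index(mask: np.ndarray) -> np.ndarray:
    """(n, 3) array of in-mask (x, y, z) coords in (z, y, x) raster order."""
    coords = np.argwhere(mask)
    order = np.lexsort((coords[:, 0], coords[:, 1], coords[:, 2]))
    return coords[order]


def build_feature_matrix(
    study: MPMRIStudy, exclude: Sequence[str] = ()
) -> FeatureMatrix:
    """Assemble the feature matrix from a rescaled study.

    Rows are ordered (raw channels, 3x3 means, 5x5 means), preserving the
    channel order within each block.  ``exclude`` drops channels before
    assembly (conventional-MRI-only ablation drops rCBV and ADC).
    """
    names = [n for n in study.channels if n not in set(exclude)]
    if not names:
        raise ValueError("no channels left after exclusion")
    mask = study.analysis_mask()
    index = _raster_index(mask)
    if index.shape[0] == 0:
        raise ValueError("no in-mask voxels in the analysed slices")
    xs, ys, zs = index[:, 0], index[:, 1], index[:, 2]

    rows: List[np.ndarray] = []
    feature_names: List[str] = []
    blocks = [("", None), ("_avg3", 3), ("_avg5", 5)]
    for suffix, k in blocks:
        for name in names:
            vol = study.channels[name]
            if k is not None:
                vol = neighborhood_average(vol, study.brain_mask, k)
            rows.append(vol[xs, ys, zs])
            feature_names.append(name + suffix)
    X = np.asarray(rows, dtype=float)
    return FeatureMatrix(
        X=X,
        feature_names=feature_names,
        voxel_index=index,
        spacing=study.spacing,
        shape=study.shape,
    )
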
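"""Segmentation quality metrics and the random-reseeding robustness protocol.

Dice overlap and the robust (95th-percentile) Hausdorff distance are
reported for the three standard tumor groupings: active tumor, tumor
core (active tumor + necrosis) and whole tumor (core + edema).
Robustness to user input is quantified by repeating the segmentation
with random seed voxels drawn from the ground-truth masks and summarising
the per-run score dispersion (quartiles, IQR, low outliers).
"""

from __future__ import annotations

import logging
import warnings
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .initialization import PATHOLOGICAL_LABELS, SeedSet

log = logging.getLogger(__name__)

GROUPINGS = ("active_tumor", "tumor_core", "whole_tumor")


def dice(A: np.ndarray, B: np.ndarray) -> float:
    """Dice overlap ``2|A n B| / (|A| + |B|)``; two empty masks give 1."""
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise ValueError(f"grid mismatch: {A.shape} vs {B.shape}")
    sa, sb = int(A.sum()), int(B.sum())
    if sa + sb == 0:
        warnings.warn("both masks empty; Dice defined as 1.0")
        return 1.0
    return 2.0 * int((A & B).sum()) / (sa + sb)


def _directed_distances(
    src: np.ndarray, dst: np.ndarray, spacing: Sequence[float]
) -> np.ndarray:
    """Distance (mm) from every voxel of ``src`` to the nearest of ``dst``."""
    dt = ndimage.distance_transform_edt(~dst, sampling=spacing)
    return dt[src]


def hausdorff95(
    A: np.ndarray, B: np.ndarray, spacing: Sequence[float] = (1.0, 1.0, 1.0)
) -> float:
    """Robust symmetric Hausdorff distance in mm (95th percentile).

    Point-to-set distances are computed over all mask voxels with
    anisotropic Euclidean distances; the result is the maximum of the
    two directed 95th percentiles (linear-interpolation estimator).
    Returns ``inf`` when either mask is empty.
    """
    return hausdorff(A, B, spacing, percentile=95.0)


def hausdorff(
    A: np.ndarray,
    B: np.ndarray,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    percentile: float = 95.0,
) -> float:
    """Symmetric percentile Hausdorff distance (100 = classic maximum)."""
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise ValueError(f"grid mismatch: {A.shape} vs {B.shape}")
    if not A.any() or not B.any():
        warnings.warn("empty mask in Hausdorff computation; returning inf")
        return float("inf")
    d_ab = _directed_distances(A, B, spacing)
    d_ba = _directed_distances(B, A, spacing)
    return float(max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile)))


def group_masks(masks: Dict[str, np.ndarray]) -> Dict[str, np.ndarray]:
    """Build the nested groupings from per-class masks.

    ``tumor_core = active_tumor | necrosis``;
    ``whole_tumor = tumor_core | edema``.
    """
    at = np.asarray(masks["active_tumor"], dtype=bool)
    core = at | np.asarray(masks.get("necrosis", np.zeros_like(at)), dtype=bool)
    whole = core | np.asarray(masks.get("edema", np.zeros_like(at)), dtype=bool)
    return {"active_tumor": at, "tumor_core": core, "whole_tumor": whole}


def evaluate(
    pred_masks: Dict[str, np.ndarray],
    truth_masks: Dict[str, np.ndarray],
    spacing: Sequence[float],
) -> pd.DataFrame:
    """Dice and HD95 per grouping, as a tidy one-row-per-grouping table."""
    gp = group_masks(pred_masks)
    gt = group_masks(truth_masks)
    rows = []
    for name in GROUPINGS:
        rows.append(
            {
                "grouping": name,
                "dice": dice(gp[name], gt[name]),
                "hausdorff95_mm": hausdorff95(gp[name], gt[name], spacing),
            }
        )
    return pd.DataFrame(rows)


def sample_seeds(
    truth_masks: Dict[str, np.ndarray],
    rng: np.random.Generator,
    points_per_region: int = 3,
) -> SeedSet:
    """Random seed voxels from each nonempty pathological truth mask.

    Emulates a user clicking ``points_per_region`` voxels per region;
    regions with fewer voxels are sampled with replacement (warned).
    """
    seeds = []
    for name in PATHOLOGICAL_LABELS:
        mask = truth_masks.get(name)
        if mask is None or not np.any(mask):
            continue
        coords = np.argwhere(mask)
        replace = coords.shape[0] < points_per_region
        if replace:
            warnings.warn(f"region {name} has fewer than {points_per_region} voxels")
        pick = rng.choice(coords.shape[0], size=points_per_region, replace=replace)
        for i in pick:
            seeds.append((tuple(int(v) for v in coords[i]), name))
    return SeedSet(seeds=seeds)


def robustness_experiment(
    study,
    truth_masks: Dict[str, np.ndarray],
    n_runs: int = 20,
    points_per_region: int = 3,
    seed: int = 0,
    segmenter: Optional[object] = None,
    **segmenter_params,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Repeat the full segmentation with random seed selections.

    Per run, ``points_per_region`` voxels are drawn uniformly from each
    nonempty pathological truth mask, the full pipeline runs, and Dice /
    HD95 are evaluated per grouping.  The summary reports quartiles, the
    IQR and low outliers (runs below ``Q1 - 1.5 IQR``).

    Returns ``(runs, summary)`` data frames.
    """
    from .pipeline import NMFSegmenter  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    records = []
    for run in range(n_runs):
        seeds = sample_seeds(truth_masks, rng, points_per_region)
        seg = segmenter if segmenter is not None else NMFSegmenter(**segmenter_params)
        result = seg.fit(study, seeds).result_
        report = evaluate(result.masks, truth_masks, study.spacing)
        for _, row in report.iterrows():
            records.append({"run": run, **row.to_dict()})
    runs = pd.DataFrame(records)

    summary_rows = []
    for grouping in GROUPINGS:
        for metric in ("dice", "hausdorff95_mm"):
            vals = runs.loc[runs.grouping == grouping, metric].to_numpy()
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            low = vals < q1 - 1.5 * iqr
            high = vals > q3 + 1.5 * iqr
            summary_rows.append(
                {
                    "grouping": grouping,
                    "metric": metric,
                    "q1": q1,
                    "median": med,
                    "q3": q3,
                    "iqr": iqr,
                    "n_low_outliers": int(low.sum()),
                    "n_high_outliers": int(high.sum()),
                    "outlier_runs": sorted(
                        runs.loc[runs.grouping == grouping, "run"].to_numpy()[low | high].tolist()
                    ),
                }
            )
    return runs, pd.DataFrame(summary_rows)
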
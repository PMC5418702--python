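"""End-to-end segmentation pipeline and run configuration.

``NMFSegmenter`` composes the stages: feature assembly (with optional
conventional-MRI-only ablation) -> in-plane downsampling -> seeded
initialization -> regularized NMF -> abundance upsampling -> argmax
labelling -> seed-driven morphological cleanup.  Everything downstream
of the user seeds is deterministic, so a run is reproducible bit-exactly
from its configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from . import __version__
from .features import (
    CMRI_EXCLUDED,
    FeatureMatrix,
    MPMRIStudy,
    build_feature_matrix,
    rescale_features,
)
from .initialization import (
    SeedSet,
    downsample_problem,
    initialize,
    snap_seeds,
    upsample_abundances,
)
from .nmf import RegularizedNMF, build_laplacian
from .postprocess import SegmentationResult, label_voxels, postprocess

log = logging.getLogger(__name__)

FEATURE_MODES = ("mp_mri", "cmri_only")


@dataclass
class RunConfig:
    """Serializable configuration of one segmentation run."""

    lam: float = 0.1
    mode: str = "spatial_sparse"
    feature_mode: str = "mp_mri"
    downsample: int = 2
    postprocess: bool = True
    max_iter: int = 500
    tol: float = 1e-6
    merge_threshold: float = 0.95
    n_normal_sources: int = 8
    random_state: int = 0

    def __post_init__(self) -> None:
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class NMFSegmenter(BaseEstimator):
    """Semi-automated tumor segmentation via seeded, regularized NMF.

    Parameters mirror :class:`RunConfig`; see the module docstring for
    the stage order.  After :meth:`fit`, ``result_`` holds the
    :class:`~nmfseg.postprocess.SegmentationResult`, ``nmf_`` the fitted
    :class:`~nmfseg.nmf.RegularizedNMF` and ``init_`` the
    :class:`~nmfseg.initialization.InitResult`.
    """

    def __init__(
        self,
        lam: float = 0.1,
        mode: str = "spatial_sparse",
        feature_mode: str = "mp_mri",
        downsample: int = 2,
        postprocess: bool = True,
        max_iter: int = 500,
        tol: float = 1e-6,
        merge_threshold: float = 0.95,
        n_normal_sources: int = 8,
        random_state: int = 0,
    ) -> None:
        self.lam = lam
        self.mode = mode
        self.feature_mode = feature_mode
        self.downsample = downsample
        self.postprocess = postprocess
        self.max_iter = max_iter
        self.tol = tol
        self.merge_threshold = merge_threshold
        self.n_normal_sources = n_normal_sources
        self.random_state = random_state

    def fit(self, study: MPMRIStudy, seeds: SeedSet):
        """Segment the study; returns ``self`` with ``result_`` set."""
        if self.feature_mode not in FEATURE_MODES:
            raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")
        timings: Dict[str, float] = {}
        t0 = time.perf_counter()
        exclude = CMRI_EXCLUDED if self.feature_mode == "cmri_only" else ()
        rescaled = rescale_features(study)
        fm_full = build_feature_matrix(rescaled, exclude=exclude)
        timings["features"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        fm = downsample_problem(fm_full, self.downsample)
        seeds_used = snap_seeds(seeds, fm) if self.downsample > 1 else seeds
        init = initialize(
            fm, seeds_used,
            merge_threshold=self.merge_threshold, n_normal=self.n_normal_sources,
        )
        timings["init"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        lap = build_laplacian(fm.voxel_index, fm.shape)
        nmf = RegularizedNMF(
            n_components=init.rank, alpha=self.lam, mode=self.mode,
            max_iter=self.max_iter, tol=self.tol, random_state=self.random_state,
        )
        nmf.fit(fm.X, W0=init.W0, H0=init.H0, laplacian=lap)
        timings["nmf"] = time.perf_counter() - t0
        log.info(
            "NMF finished: %d iterations, final objective %.6g, converged=%s",
            nmf.n_iter_, nmf.objective_trace_[-1], nmf.converged_,
        )

        t0 = time.perf_counter()
        H_full = upsample_abundances(nmf.H_, fm, fm_full, self.downsample)
        scales = np.linalg.norm(nmf.W_, axis=0)
        prelim = label_voxels(
            H_full, init.source_labels, fm_full.voxel_index, fm_full.shape,
            source_scales=scales,
        )
        result = postprocess(prelim, seeds, study.spacing, voxel_index=fm_full.voxel_index)
        if not self.postprocess:
            # ablation: keep the preliminary masks as the final answer
            result = SegmentationResult(
                masks=dict(prelim),
                preliminary_masks=dict(prelim),
                voxel_index=fm_full.voxel_index,
                spacing=tuple(study.spacing),
                provenance={"postprocess": "disabled"},
            )
        timings["postprocess"] = time.perf_counter() - t0

        result.diagnostics = {
            "n_iter": int(nmf.n_iter_),
            "converged": bool(nmf.converged_),
            "objective_final": float(nmf.objective_trace_[-1]),
            "rank": init.rank,
            "n_voxels": fm.n_voxels,
            "timings_s": timings,
        }
        self.feature_matrix_ = fm_full
        self.init_ = init
        self.nmf_ = nmf
        self.abundances_ = H_full
        self.result_ = result
        return self

    def predict(self, study: Optional[MPMRIStudy] = None) -> np.ndarray:
        """Combined integer label volume of the fitted study."""
        if not hasattr(self, "result_"):
            raise AttributeError("NMFSegmenter instance is not fitted yet")
        return self.result_.label_volume()

    def run_config(self) -> RunConfig:
        return RunConfig(**self.get_params())


def segment(
    study: MPMRIStudy, seeds: SeedSet, config: Optional[RunConfig] = None
) -> Tuple[SegmentationResult, dict]:
    """Run one configured segmentation; returns (result, manifest).

    The manifest records the configuration hash, package version, the
    seeds used and solver diagnostics -- enough to reproduce the run.
    """
    config = config or RunConfig()
    seg = NMFSegmenter(**asdict(config))
    seg.fit(study, seeds)
    trace = seg.nmf_.objective_trace_
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seeds": [
            {"x": int(c[0]), "y": int(c[1]), "z": int(c[2]), "label": lb}
            for c, lb in seeds.seeds
        ],
        "diagnostics": seg.result_.diagnostics,
        "objective_trace_tail": [float(v) for v in trace[-5:]],
    }
    return seg.result_, manifest
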
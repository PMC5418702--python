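"""Deterministic initialization of the NMF factors.

Pathological sources come from user-selected seed voxels (feature vector
averaged with the in-plane 4-neighbours, then near-duplicates merged by
correlation).  Normal-tissue sources are found automatically: the
successive projection algorithm (SPA) picks eight maximally non-collinear
voxels after deflating the pathological span, and a fuzzy C-means pass
with *frozen* pathological centroids refines them against outliers.
``H0`` is the per-voxel non-negative least-squares fit against ``W0``.
The whole procedure is deterministic given the seeds, so repeated runs
are bit-identical.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.optimize import nnls

from .features import FeatureMatrix

log = logging.getLogger(__name__)

PATHOLOGICAL_LABELS = ("active_tumor", "necrosis", "edema")
N_NORMAL_SOURCES = 8  # two sources for each of WM, GM, CSF, vessels


@dataclass
class SeedSet:
    """User-selected voxels with pathological tissue labels.

    ``seeds`` is a list of ``((x, y, z), label)`` with 0-based voxel
    coordinates on the NIfTI grid.
    """

    seeds: List[Tuple[Tuple[int, int, int], str]]

    def __post_init__(self) -> None:
        for coord, label in self.seeds:
            if label not in PATHOLOGICAL_LABELS:
                raise ValueError(
                    f"seed label {label!r} not in {PATHOLOGICAL_LABELS}"
                )
        if "active_tumor" not in {lb for _, lb in self.seeds}:
            raise ValueError("at least one active_tumor seed is required")

    def by_label(self) -> Dict[str, List[Tuple[int, int, int]]]:
        out: Dict[str, List[Tuple[int, int, int]]] = {}
        for coord, label in self.seeds:
            out.setdefault(label, []).append(tuple(coord))
        return out

    @property
    def labels(self) -> List[str]:
        return [lb for _, lb in self.seeds]


@dataclass
class InitResult:
    """Initial factors with per-source labels and seed provenance."""

    W0: np.ndarray
    H0: np.ndarray
    source_labels: List[str]
    seed_provenance: List[List[int]] = field(default_factory=list)

    @property
    def rank(self) -> int:
        return self.W0.shape[1]


def _neighbour_average(
    X: np.ndarray, lookup: Dict[Tuple[int, int, int], int], coord: Tuple[int, int, int]
) -> np.ndarray:
    """Mean feature vector of a voxel and its in-plane 4-neighbours in X."""
    x, y, z = coord
    cols = []
    for dx, dy in ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)):
        j = lookup.get((x + dx, y + dy, z))
        if j is not None:
            cols.append(j)
    return X[:, cols].mean(axis=1)


def seed_sources(
    X: np.ndarray, voxel_index: np.ndarray, seeds: SeedSet
) -> Tuple[np.ndarray, List[str]]:
    """One candidate source vector per seed.

    Each candidate is the mean of the feature columns of the seed voxel
    and those of its in-plane 4-neighbours that are columns of ``X``.
    """
    lookup = {tuple(c): j for j, c in enumerate(map(tuple, np.asarray(voxel_index)))}
    candidates = []
    labels = []
    for coord, label in seeds.seeds:
        coord = tuple(int(c) for c in coord)
        if coord not in lookup:
            raise ValueError(f"seed {coord} ({label}) is not a voxel of the feature matrix")
        candidates.append(_neighbour_average(X, lookup, coord))
        labels.append(label)
    return np.column_stack(candidates), labels


def merge_candidates(
    candidates: np.ndarray, labels: Sequence[str], threshold: float = 0.95
) -> Tuple[np.ndarray, List[str], List[List[int]]]:
    """Merge highly correlated candidates within each tissue label.

    Similarity is the inner product of the L2-normalised vectors.
    Within one label, candidates are grouped by single linkage over
    pairs with similarity above ``threshold`` and each group is replaced
    by the unnormalised mean of its members; labels never mix.

    Returns the merged sources, their labels, and the candidate indices
    merged into each source.
    """
    candidates = np.asarray(candidates, dtype=float)
    norms = np.linalg.norm(candidates, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero-norm candidate source vector")
    unit = candidates / norms

    merged_cols: List[np.ndarray] = []
    merged_labels: List[str] = []
    provenance: List[List[int]] = []
    for label in dict.fromkeys(labels):  # preserve first-appearance order
        idx = [i for i, lb in enumerate(labels) if lb == label]
        sim = unit[:, idx].T @ unit[:, idx]
        # single-linkage components over the similarity graph
        parent = list(range(len(idx)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                if sim[a, b] > threshold:
                    parent[find(a)] = find(b)
        groups: Dict[int, List[int]] = {}
        for a in range(len(idx)):
            groups.setdefault(find(a), []).append(idx[a])
        for members in groups.values():
            merged_cols.append(candidates[:, members].mean(axis=1))
            merged_labels.append(label)
            provenance.append(members)
    return np.column_stack(merged_cols), merged_labels, provenance


def spa_select(
    X: np.ndarray, pathological_sources: Optional[np.ndarray], k: int = N_NORMAL_SOURCES
) -> List[int]:
    """Successive projection algorithm: pick ``k`` non-collinear columns.

    All columns are first projected onto the orthogonal complement of the
    pathological-source span; the column with the largest residual
    L2-norm is picked, the matrix is deflated against it, and the loop
    repeats (cumulative deflation) until ``k`` columns are selected.
    """
    if k > X.shape[1]:
        raise ValueError(f"cannot select {k} voxels from {X.shape[1]} columns")
    P = np.array(X, dtype=float, copy=True)
    if pathological_sources is not None and pathological_sources.size:
        Q, _ = np.linalg.qr(np.asarray(pathological_sources, dtype=float))
        P -= Q @ (Q.T @ P)
    scale = float(np.max(np.sum(P * P, axis=0)))
    if scale == 0:
        raise ValueError("all columns lie in the span of the pathological sources")
    picked: List[int] = []
    for _ in range(k):
        norms = np.sum(P * P, axis=0)
        j = int(np.argmax(norms))
        if norms[j] <= 1e-12 * scale:
            raise ValueError(
                f"rank collapse after {len(picked)} picks: residual norms vanished"
            )
        picked.append(j)
        v = P[:, j].copy()
        P -= np.outer(v, (v @ P) / float(np.dot(v, v)))
    return picked


def fcm_refine(
    X: np.ndarray,
    pathological_sources: np.ndarray,
    normal_init: np.ndarray,
    fuzziness: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 100,
) -> np.ndarray:
    """Fuzzy C-means with frozen pathological centroids.

    Memberships are updated for all centroids, but only the normal
    centroids are recomputed; the pathological columns of the result are
    bit-identical to the input.  Deterministic (no random init).
    """
    n_path = pathological_sources.shape[1] if pathological_sources.size else 0
    C = np.column_stack([pathological_sources, normal_init]) if n_path else np.array(
        normal_init, copy=True
    )
    C = np.asarray(C, dtype=float)
    c = C.shape[1]
    expo = 2.0 / (fuzziness - 1.0)
    for _ in range(max_iter):
        # squared distances (c, n)
        d2 = (
            np.sum(C * C, axis=0)[:, None]
            - 2.0 * C.T @ X
            + np.sum(X * X, axis=0)[None, :]
        )
        d2 = np.maximum(d2, 0.0)
        zero = d2 < 1e-30
        any_zero = zero.any(axis=0)
        with np.errstate(divide="ignore"):
            inv = d2 ** (-expo / 2.0)
        u = np.where(any_zero[None, :], zero / np.maximum(zero.sum(axis=0), 1), 0.0)
        ok = ~any_zero
        u[:, ok] = inv[:, ok] / inv[:, ok].sum(axis=0)

        um = u**fuzziness
        C_new = np.array(C, copy=True)
        for i in range(n_path, c):
            denom = um[i].sum()
            if denom <= 1e-30:
                warnings.warn(f"FCM cluster {i} is empty; centroid kept")
                continue
            C_new[:, i] = (X @ um[i]) / denom
        shift = float(np.max(np.linalg.norm(C_new - C, axis=0)))
        C = C_new
        if shift < tol:
            break
    return C


def init_H(X: np.ndarray, W0: np.ndarray) -> np.ndarray:
    """Per-column non-negative least squares: ``min_{h>=0} ||x_j - W0 h||``."""
    r = W0.shape[1]
    H0 = np.empty((r, X.shape[1]))
    # many columns repeat on piecewise-constant data; cache exact repeats
    seen: Dict[bytes, np.ndarray] = {}
    for j in range(X.shape[1]):
        key = X[:, j].tobytes()
        h = seen.get(key)
        if h is None:
            h = nnls(W0, X[:, j])[0]
            seen[key] = h
        H0[:, j] = h
    return H0


#: cosine above which a refined normal centroid is considered a duplicate
#: of a seeded pathological source (stricter than the 0.95 within-class
#: merge threshold because all-positive feature vectors correlate highly)
DUPLICATE_SOURCE_COSINE = 0.99


def relabel_duplicate_sources(
    W0: np.ndarray,
    labels: Sequence[str],
    n_pathological: int,
    threshold: float = DUPLICATE_SOURCE_COSINE,
) -> List[str]:
    """Give pathological labels to normal sources that duplicate one.

    SPA is sensitive to outliers and may seed a "normal" centroid inside
    a pathological region; frozen-centroid FCM cannot pull it out, so
    the refined centroid ends up a near-copy of a seeded pathological
    signature and would silently steal that tissue's voxels at the
    abundance argmax.  Any normal source whose cosine similarity to a
    pathological source exceeds ``threshold`` therefore inherits that
    source's label; downstream label pooling merges them.
    """
    labels = list(labels)
    unit = W0 / np.linalg.norm(W0, axis=0)
    for s in range(n_pathological, W0.shape[1]):
        cos = unit[:, :n_pathological].T @ unit[:, s]
        best = int(np.argmax(cos))
        if cos[best] > threshold:
            log.info(
                "normal source %d duplicates %s source (cosine %.4f); relabeled",
                s, labels[best], cos[best],
            )
            labels[s] = labels[best]
    return labels


def initialize(
    fm: FeatureMatrix,
    seeds: SeedSet,
    merge_threshold: float = 0.95,
    n_normal: int = N_NORMAL_SOURCES,
) -> InitResult:
    """Full initialization pipeline: seeds -> merge -> SPA -> FCM -> NNLS."""
    cand, cand_labels = seed_sources(fm.X, fm.voxel_index, seeds)
    path_W, path_labels, provenance = merge_candidates(cand, cand_labels, merge_threshold)
    spa_idx = spa_select(fm.X, path_W, k=n_normal)
    lookup = fm.column_lookup()
    normal_init = np.column_stack(
        [_neighbour_average(fm.X, lookup, tuple(fm.voxel_index[j])) for j in spa_idx]
    )
    W0 = fcm_refine(fm.X, path_W, normal_init)
    labels = path_labels + ["normal"] * n_normal
    labels = relabel_duplicate_sources(W0, labels, len(path_labels))
    H0 = init_H(fm.X, W0)
    return InitResult(W0=W0, H0=H0, source_labels=labels, seed_provenance=provenance)


# -- in-plane downsampling ---------------------------------------------------


def downsample_problem(fm: FeatureMatrix, factor: int = 2) -> FeatureMatrix:
    """Retain columns at every ``factor``-th in-plane grid position.

    The z direction is untouched.  ``factor == 1`` returns the input.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError(f"factor must be a positive integer, got {factor}")
    if factor == 1:
        return fm
    keep = (fm.voxel_index[:, 0] % factor == 0) & (fm.voxel_index[:, 1] % factor == 0)
    return FeatureMatrix(
        X=fm.X[:, keep],
        feature_names=fm.feature_names,
        voxel_index=fm.voxel_index[keep],
        spacing=fm.spacing,
        shape=fm.shape,
    )


def snap_seeds(seeds: SeedSet, fm_down: FeatureMatrix) -> SeedSet:
    """Snap seed voxels to the nearest retained in-plane grid position.

    Seeds already on retained columns are unchanged; otherwise the
    closest retained column in the same slice is used (warning if the
    seed's slice lost all columns -- then the globally nearest column
    wins).
    """
    lookup = fm_down.column_lookup()
    vi = fm_down.voxel_index
    snapped = []
    for coord, label in seeds.seeds:
        coord = tuple(int(c) for c in coord)
        if coord in lookup:
            snapped.append((coord, label))
            continue
        same_z = vi[vi[:, 2] == coord[2]]
        pool = same_z
        if same_z.shape[0] == 0:
            warnings.warn(f"slice {coord[2]} has no retained voxels; snapping in 3D")
            pool = vi
        d2 = np.sum((pool - np.asarray(coord)) ** 2, axis=1)
        snapped.append((tuple(int(v) for v in pool[int(np.argmin(d2))]), label))
    return SeedSet(seeds=snapped)


def upsample_abundances(
    H: np.ndarray, fm_down: FeatureMatrix, fm_full: FeatureMatrix, factor: int = 2
) -> np.ndarray:
    """Bilinearly interpolate abundance maps back to all in-mask voxels.

    Each source's abundance map is placed on the coarse in-plane grid,
    holes (coarse cells outside the mask) are nearest-filled so boundary
    voxels interpolate from valid values, and the map is sampled at the
    full-resolution voxel positions with in-plane bilinear interpolation.
    ``factor == 1`` is the identity.
    """
    if factor == 1:
        return H
    r = H.shape[0]
    nx, ny, nz = fm_full.shape
    ncx = (nx + factor - 1) // factor
    ncy = (ny + factor - 1) // factor
    out = np.zeros((r, fm_full.n_voxels))
    vi_d = fm_down.voxel_index
    vi_f = fm_full.voxel_index
    for z in range(nz):
        sel_d = np.nonzero(vi_d[:, 2] == z)[0]
        sel_f = np.nonzero(vi_f[:, 2] == z)[0]
        if sel_f.size == 0:
            continue
        if sel_d.size == 0:
            warnings.warn(f"slice {z} has no coarse voxels; abundances left 0")
            continue
        cx = vi_d[sel_d, 0] // factor
        cy = vi_d[sel_d, 1] // factor
        filled = np.zeros((ncx, ncy), dtype=bool)
        filled[cx, cy] = True
        # nearest-neighbour fill of empty coarse cells
        _, (ix, iy) = ndimage.distance_transform_edt(~filled, return_indices=True)
        fx = vi_f[sel_f, 0] / factor
        fy = vi_f[sel_f, 1] / factor
        coords = np.vstack([fx, fy])
        for s in range(r):
            grid = np.zeros((ncx, ncy))
            grid[cx, cy] = H[s, sel_d]
            grid = grid[ix, iy]
            out[s, sel_f] = ndimage.map_coordinates(grid, coords, order=1, mode="nearest")
    return out
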
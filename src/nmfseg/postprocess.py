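"""Label assignment and connected-component morphological cleanup.

Each voxel is assigned to the source with the highest abundance; sources
sharing a pathological label are pooled.  Cleanup then exploits the
user's seed locations: step 1 keeps, per pathological class, only the
3D-connected component(s) nearest to each seed (Euclidean distance in mm,
honouring anisotropic spacing); step 2 restores preliminary components
that are face-adjacent to a retained component of the partner class
(necrosis next to active tumor, active tumor next to necrosis, edema
next to active tumor), so unseeded satellites of a lesion survive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .initialization import PATHOLOGICAL_LABELS, SeedSet

log = logging.getLogger(__name__)

TISSUE_CLASSES = ("normal",) + PATHOLOGICAL_LABELS
#: integer ids in the combined label volume
TISSUE_IDS = {"normal": 0, "active_tumor": 1, "necrosis": 2, "edema": 3}

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class SegmentationResult:
    """Per-tissue masks before and after morphological cleanup."""

    masks: Dict[str, np.ndarray]
    preliminary_masks: Dict[str, np.ndarray]
    voxel_index: np.ndarray
    spacing: Tuple[float, float, float]
    provenance: Dict[str, dict] = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def label_volume(self) -> np.ndarray:
        """Combined integer label volume (0 normal .. 3 edema)."""
        vol = np.zeros(self.masks["normal"].shape, dtype=np.int16)
        for name in PATHOLOGICAL_LABELS:
            vol[self.masks[name]] = TISSUE_IDS[name]
        return vol


def label_voxels(
    H: np.ndarray,
    source_labels: Sequence[str],
    voxel_index: np.ndarray,
    shape: Tuple[int, int, int],
    source_scales: Optional[np.ndarray] = None,
) -> Dict[str, np.ndarray]:
    """Preliminary per-tissue masks from the per-voxel abundance argmax.

    Ties break to the lowest source index; sources with the same label
    are pooled into one mask.  All-zero columns go to "normal" (warned).

    ``source_scales`` (typically the L2 norms of the fitted ``W``
    columns) weights each abundance row before the argmax.  The NMF
    scaling between a source column and its abundance row is arbitrary
    (``w_i h_i = (c w_i)(h_i / c)``), so the comparison across sources is
    only meaningful for the signal contribution ``|w_i| h_ij``; with the
    scales supplied the labelling is invariant to any compensating
    per-source rescaling of the factors.
    """
    H = np.asarray(H)
    if (H < 0).any():
        raise ValueError("abundances must be non-negative")
    scored = H if source_scales is None else H * np.asarray(source_scales)[:, None]
    winner = np.argmax(scored, axis=0)  # lowest index wins ties
    dead = ~np.any(H > 0, axis=0)
    if dead.any():
        warnings.warn(f"{int(dead.sum())} voxels with all-zero abundances set to normal")
    labels = np.asarray([source_labels[i] for i in winner], dtype=object)
    labels[dead] = "normal"
    masks: Dict[str, np.ndarray] = {}
    xs, ys, zs = voxel_index[:, 0], voxel_index[:, 1], voxel_index[:, 2]
    for name in TISSUE_CLASSES:
        m = np.zeros(shape, dtype=bool)
        m[xs[labels == name], ys[labels == name], zs[labels == name]] = True
        masks[name] = m
    return masks


def retain_nearest_components(
    mask: np.ndarray,
    seeds: Sequence[Tuple[int, int, int]],
    spacing: Tuple[float, float, float],
) -> Tuple[np.ndarray, List[int]]:
    """Keep only the connected component(s) nearest to each seed.

    Components use 26-connectivity.  The seed-to-component distance is
    the minimum over component voxels of the Euclidean distance in mm;
    exact ties retain every tying component.  Returns the retained mask
    and the retained component ids.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        if seeds:
            warnings.warn("empty mask with seeds present; nothing retained")
        return mask.copy(), []
    labeled, n_comp = ndimage.label(mask, structure=_STRUCT_26)
    coords = {i: np.argwhere(labeled == i) for i in range(1, n_comp + 1)}
    sp = np.asarray(spacing, dtype=float)
    retained: set = set()
    for seed in seeds:
        seed_mm = np.asarray(seed, dtype=float) * sp
        dists = {}
        for i, pts in coords.items():
            d = np.linalg.norm(pts * sp - seed_mm, axis=1)
            dists[i] = float(d.min())
        best = min(dists.values())
        retained.update(i for i, d in dists.items() if d <= best + 1e-9)
    out = np.isin(labeled, sorted(retained))
    return out, sorted(retained)


def recover_adjacent_components(
    step1_masks: Dict[str, np.ndarray],
    preliminary_masks: Dict[str, np.ndarray],
) -> Tuple[Dict[str, np.ndarray], Dict[str, List[int]]]:
    """Restore preliminary components adjacent to retained partner tissue.

    Applied once, in order: necrosis <- active tumor, active tumor <-
    necrosis, edema <- active tumor.  Adjacency is face-sharing
    (6-neighbourhood) with the *step-1* retained partner mask, so corner
    contact does not count and the order cannot cascade.
    """
    rules = [("necrosis", "active_tumor"), ("active_tumor", "necrosis"), ("edema", "active_tumor")]
    final = {k: v.copy() for k, v in step1_masks.items()}
    recovered: Dict[str, List[int]] = {k: [] for k, _ in rules}
    for target, partner in rules:
        partner_mask = step1_masks.get(partner)
        prelim = preliminary_masks.get(target)
        if partner_mask is None or prelim is None or not partner_mask.any():
            continue
        touch = ndimage.binary_dilation(partner_mask, structure=_STRUCT_6)
        labeled, n_comp = ndimage.label(prelim, structure=_STRUCT_26)
        for i in range(1, n_comp + 1):
            comp = labeled == i
            if np.any(comp & final[target]):
                continue  # already retained
            if np.any(comp & touch):
                final[target] |= comp
                recovered[target].append(i)
    return final, recovered


def postprocess(
    preliminary_masks: Dict[str, np.ndarray],
    seeds: SeedSet,
    spacing: Tuple[float, float, float],
    voxel_index: Optional[np.ndarray] = None,
) -> SegmentationResult:
    """Run the two-step cleanup on preliminary masks.

    Pathological classes without seeds keep their preliminary mask only
    through step-2 recovery (no seed means step 1 retains nothing for
    that class).  Normal tissue is everything not pathological.
    """
    by_label = seeds.by_label()
    step1: Dict[str, np.ndarray] = {}
    provenance: Dict[str, dict] = {}
    for name in PATHOLOGICAL_LABELS:
        prelim = preliminary_masks.get(name, None)
        if prelim is None:
            continue
        if name in by_label:
            kept, ids = retain_nearest_components(prelim, by_label[name], spacing)
            step1[name] = kept
            provenance[name] = {"retained_components": ids}
        else:
            step1[name] = np.zeros_like(prelim)
            provenance[name] = {"retained_components": []}
    final, recovered = recover_adjacent_components(step1, preliminary_masks)
    for name, ids in recovered.items():
        provenance.setdefault(name, {})["recovered_components"] = ids

    masks = {name: final.get(name, np.zeros_like(preliminary_masks[name])) for name in PATHOLOGICAL_LABELS}
    analyzed = np.zeros_like(preliminary_masks["normal"])
    for m in preliminary_masks.values():
        analyzed |= m
    normal = analyzed.copy()
    for m in masks.values():
        normal &= ~m
    masks["normal"] = normal
    if voxel_index is None:
        voxel_index = np.argwhere(analyzed)
    return SegmentationResult(
        masks=masks,
        preliminary_masks=dict(preliminary_masks),
        voxel_index=voxel_index,
        spacing=tuple(spacing),
        provenance=provenance,
    )
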
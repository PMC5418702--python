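"""Argmax labelling and the two-step connected-component cleanup."""

import numpy as np
import pytest

from nmfseg.initialization import SeedSet
from nmfseg.postprocess import (
    label_voxels,
    postprocess,
    recover_adjacent_components,
    retain_nearest_components,
)

SP = (1.0, 1.0, 3.0)


class TestLabelVoxels:
    def _vi(self, n):
        return np.array([(i, 0, 0) for i in range(n)])

    def test_one_hot_column_gets_that_source_label(self):
        H = np.array([[1.0], [0.0], [0.0]])
        masks = label_voxels(H, ["edema", "necrosis", "normal"], self._vi(1), (1, 1, 1))
        assert masks["edema"][0, 0, 0]

    def test_per_source_not_per_class_argmax(self):
        # two active-tumor sources at 0.3 / 0.4 vs one normal at 0.35:
        # the single best source (0.4) wins, not the class sum
        H = np.array([[0.3], [0.4], [0.35]])
        masks = label_voxels(
            H, ["active_tumor", "active_tumor", "normal"], self._vi(1), (1, 1, 1)
        )
        assert masks["active_tumor"][0, 0, 0]
        # and pooled: both active-tumor sources map into one mask
        H2 = np.array([[0.5, 0.1], [0.1, 0.6], [0.2, 0.2]])
        masks2 = label_voxels(
            H2, ["active_tumor", "active_tumor", "normal"], self._vi(2), (2, 1, 1)
        )
        assert masks2["active_tumor"].sum() == 2

    def test_exact_tie_breaks_to_lowest_source_index(self):
        H = np.array([[0.5], [0.2], [0.5]])
        masks = label_voxels(H, ["edema", "normal", "necrosis"], self._vi(1), (1, 1, 1))
        assert masks["edema"][0, 0, 0] and not masks["necrosis"][0, 0, 0]

    def test_all_zero_column_is_normal_with_warning(self):
        H = np.zeros((2, 1))
        with pytest.warns(UserWarning, match="all-zero"):
            masks = label_voxels(H, ["edema", "necrosis"], self._vi(1), (1, 1, 1))
        assert masks["normal"][0, 0, 0]


class TestRetainNearest:
    def test_component_containing_seed_unchanged(self):
        mask = np.zeros((6, 6, 2), bool)
        mask[1:3, 1:3, 0] = True
        out, ids = retain_nearest_components(mask, [(1, 1, 0)], SP)
        assert np.array_equal(out, mask) and len(ids) == 1

    def test_other_component_removed(self):
        mask = np.zeros((8, 8, 1), bool)
        mask[0:2, 0:2, 0] = True
        mask[6:8, 6:8, 0] = True
        out, _ = retain_nearest_components(mask, [(0, 0, 0)], SP)
        assert out[0, 0, 0] and not out[7, 7, 0]

    def test_anisotropic_spacing_decides_in_millimetres(self):
        # seed at origin; component A two slices away (2 voxel steps = 6 mm),
        # component B five in-plane steps away (5 mm): B is nearer in mm
        mask = np.zeros((8, 8, 3), bool)
        mask[0, 0, 2] = True  # A
        mask[0, 5, 0] = True  # B
        out, _ = retain_nearest_components(mask, [(0, 0, 0)], SP)
        assert out[0, 5, 0] and not out[0, 0, 2]
        # with isotropic 1 mm spacing the decision flips to A
        out_iso, _ = retain_nearest_components(mask, [(0, 0, 0)], (1, 1, 1))
        assert out_iso[0, 0, 2] and not out_iso[0, 5, 0]

    def test_union_over_seeds_and_empty_mask_warning(self):
        mask = np.zeros((8, 8, 1), bool)
        mask[0:2, 0:2, 0] = True
        mask[6:8, 6:8, 0] = True
        out, ids = retain_nearest_components(mask, [(0, 0, 0), (7, 7, 0)], SP)
        assert np.array_equal(out, mask) and len(ids) == 2
        with pytest.warns(UserWarning, match="empty mask"):
            out2, ids2 = retain_nearest_components(np.zeros((4, 4, 1), bool), [(0, 0, 0)], SP)
        assert not out2.any() and ids2 == []

    def test_retained_component_holds_nearest_voxel_bruteforce(self, rng):
        # brute-force assertion of the step-1 contract on random masks
        from scipy import ndimage

        for _ in range(5):
            mask = rng.uniform(size=(10, 10, 3)) > 0.8
            if not mask.any():
                continue
            seed = (int(rng.integers(10)), int(rng.integers(10)), int(rng.integers(3)))
            out, _ = retain_nearest_components(mask, [seed], SP)
            coords = np.argwhere(mask) * np.array(SP)
            d = np.linalg.norm(coords - np.array(seed) * np.array(SP), axis=1)
            nearest_voxel = np.argwhere(mask)[int(np.argmin(d))]
            assert out[tuple(nearest_voxel)]


class TestRecoverAdjacent:
    def _masks(self):
        shape = (10, 10, 2)
        prelim = {k: np.zeros(shape, bool) for k in
                  ("normal", "active_tumor", "necrosis", "edema")}
        return shape, prelim

    def test_unseeded_necrosis_adjacent_to_tumor_recovered(self):
        shape, prelim = self._masks()
        prelim["active_tumor"][2:5, 2:5, 0] = True
        prelim["necrosis"][5, 3, 0] = True  # face-adjacent satellite
        step1 = {k: v.copy() for k, v in prelim.items()}
        step1["necrosis"][:] = False  # not retained by any seed
        final, rec = recover_adjacent_components(step1, prelim)
        assert final["necrosis"][5, 3, 0]
        assert rec["necrosis"] == [1]

    def test_isolated_component_stays_removed(self):
        shape, prelim = self._masks()
        prelim["active_tumor"][2:4, 2:4, 0] = True
        prelim["necrosis"][8, 8, 1] = True
        step1 = {k: v.copy() for k, v in prelim.items()}
        step1["necrosis"][:] = False
        final, _ = recover_adjacent_components(step1, prelim)
        assert not final["necrosis"].any()

    def test_corner_contact_does_not_count_as_adjacency(self):
        shape, prelim = self._masks()
        prelim["active_tumor"][3, 3, 0] = True
        prelim["necrosis"][4, 4, 0] = True  # diagonal-only contact
        step1 = {k: v.copy() for k, v in prelim.items()}
        step1["necrosis"][:] = False
        final, _ = recover_adjacent_components(step1, prelim)
        assert not final["necrosis"].any()

    def test_edema_recovers_via_active_tumor_only(self):
        shape, prelim = self._masks()
        prelim["necrosis"][2:4, 2:4, 0] = True
        prelim["edema"][4, 2, 0] = True  # touches necrosis, not active tumor
        step1 = {k: v.copy() for k, v in prelim.items()}
        step1["edema"][:] = False
        final, _ = recover_adjacent_components(step1, prelim)
        assert not final["edema"].any()


class TestPostprocessPipeline:
    def test_monotone_shrinking_and_partition(self):
        shape = (12, 12, 2)
        prelim = {k: np.zeros(shape, bool) for k in
                  ("normal", "active_tumor", "necrosis", "edema")}
        prelim["active_tumor"][2:5, 2:5, :] = True
        prelim["active_tumor"][9:11, 9:11, :] = True  # far false positive
        prelim["necrosis"][3, 3, 0] = False
        prelim["edema"][5:7, 2:5, :] = True
        prelim["normal"] = ~(prelim["active_tumor"] | prelim["edema"])
        seeds = SeedSet(seeds=[((2, 2, 0), "active_tumor"), ((5, 3, 0), "edema")])
        res = postprocess(prelim, seeds, SP)
        for name in ("active_tumor", "necrosis", "edema"):
            assert np.all(prelim[name] | ~res.masks[name])  # final <= prelim
        assert not res.masks["active_tumor"][9, 9, 0]  # false positive removed
        # masks partition the analysed voxels
        total = np.zeros(shape, int)
        for m in res.masks.values():
            total += m.astype(int)
        analysed = np.zeros(shape, bool)
        for m in prelim.values():
            analysed |= m
        assert np.array_equal(total > 0, analysed)
        assert np.all(total <= 1)

    def test_independent_of_seed_order(self):
        shape = (10, 10, 1)
        prelim = {k: np.zeros(shape, bool) for k in
                  ("normal", "active_tumor", "necrosis", "edema")}
        prelim["active_tumor"][1:3, 1:3, 0] = True
        prelim["active_tumor"][7:9, 7:9, 0] = True
        prelim["normal"] = ~prelim["active_tumor"]
        s1 = SeedSet(seeds=[((1, 1, 0), "active_tumor"), ((8, 8, 0), "active_tumor")])
        s2 = SeedSet(seeds=list(reversed(s1.seeds)))
        r1 = postprocess(prelim, s1, SP)
        r2 = postprocess(prelim, s2, SP)
        assert np.array_equal(r1.masks["active_tumor"], r2.masks["active_tumor"])
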
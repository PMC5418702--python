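"""Seeded source construction, SPA, frozen-centroid FCM, NNLS and resampling."""

import itertools

import numpy as np
import pytest

from nmfseg.features import FeatureMatrix, build_feature_matrix, rescale_features
from nmfseg.initialization import (
    SeedSet,
    downsample_problem,
    fcm_refine,
    init_H,
    initialize,
    merge_candidates,
    seed_sources,
    snap_seeds,
    spa_select,
    upsample_abundances,
)


def _fm(X, voxel_index, shape):
    return FeatureMatrix(
        X=np.asarray(X, float),
        feature_names=[f"f{i}" for i in range(np.asarray(X).shape[0])],
        voxel_index=np.asarray(voxel_index),
        spacing=(1.0, 1.0, 3.0),
        shape=shape,
    )


def _grid_fm(rng, nx=5, ny=5, nz=1, m=4):
    vi = np.array([(x, y, z) for z in range(nz) for y in range(ny) for x in range(nx)])
    X = rng.uniform(0.1, 1.0, size=(m, len(vi)))
    return _fm(X, vi, (nx, ny, nz))


class TestSeedSources:
    def test_constant_region_returns_own_feature_vector(self, rng):
        fm = _grid_fm(rng)
        fm.X[:, :] = fm.X[:, [0]]  # constant image
        seeds = SeedSet(seeds=[((2, 2, 0), "active_tumor")])
        cand, labels = seed_sources(fm.X, fm.voxel_index, seeds)
        assert np.allclose(cand[:, 0], fm.X[:, 0])
        assert labels == ["active_tumor"]

    def test_boundary_seed_averages_available_neighbors_only(self, rng):
        fm = _grid_fm(rng)
        lookup = fm.column_lookup()
        seeds = SeedSet(seeds=[((0, 0, 0), "active_tumor")])
        cand, _ = seed_sources(fm.X, fm.voxel_index, seeds)
        cols = [lookup[(0, 0, 0)], lookup[(1, 0, 0)], lookup[(0, 1, 0)]]
        assert np.allclose(cand[:, 0], fm.X[:, cols].mean(axis=1))

    def test_duplicate_seeds_give_identical_candidates(self, rng):
        fm = _grid_fm(rng)
        seeds = SeedSet(
            seeds=[((2, 2, 0), "active_tumor"), ((2, 2, 0), "active_tumor")]
        )
        cand, _ = seed_sources(fm.X, fm.voxel_index, seeds)
        assert np.array_equal(cand[:, 0], cand[:, 1])

    def test_seed_outside_matrix_named_in_error(self, rng):
        fm = _grid_fm(rng)
        seeds = SeedSet(seeds=[((4, 4, 3), "active_tumor")])
        with pytest.raises(ValueError, match=r"\(4, 4, 3\)"):
            seed_sources(fm.X, fm.voxel_index, seeds)


class TestMergeCandidates:
    def test_identical_candidates_merge_to_one(self):
        v = np.array([[1.0, 1.0], [2.0, 2.0], [0.5, 0.5]])
        W, labels, prov = merge_candidates(v, ["edema", "edema"])
        assert W.shape[1] == 1 and labels == ["edema"]
        assert np.allclose(W[:, 0], v[:, 0])
        assert sorted(prov[0]) == [0, 1]

    def test_orthogonal_candidates_stay_separate(self):
        v = np.array([[1.0, 0.0], [0.0, 1.0]])
        W, labels, _ = merge_candidates(v, ["necrosis", "necrosis"])
        assert W.shape[1] == 2

    def test_single_linkage_chains_prescribed_cosines(self):
        # pairwise cosines (v1,v2)=0.96, (v2,v3)=0.96, (v1,v3)=0.90
        v1 = np.array([1.0, 0.0, 0.0])
        v2 = np.array([0.96, np.sqrt(1 - 0.96**2), 0.0])
        b = (0.96 - 0.96 * 0.90) / np.sqrt(1 - 0.96**2)
        v3 = np.array([0.90, b, np.sqrt(1 - 0.81 - b * b)])
        V = np.column_stack([v1, v2, v3])
        cos = (V / np.linalg.norm(V, axis=0)).T @ (V / np.linalg.norm(V, axis=0))
        assert cos[0, 1] == pytest.approx(0.96) and cos[1, 2] == pytest.approx(0.96)
        assert cos[0, 2] == pytest.approx(0.90)
        W, labels, prov = merge_candidates(V, ["edema"] * 3)
        assert W.shape[1] == 1  # chained through the middle vector
        assert sorted(prov[0]) == [0, 1, 2]

    def test_never_merges_across_labels(self):
        v = np.column_stack([np.ones(3), np.ones(3)])
        W, labels, _ = merge_candidates(v, ["active_tumor", "necrosis"])
        assert W.shape[1] == 2
        assert set(labels) == {"active_tumor", "necrosis"}

    def test_zero_norm_candidate_rejected(self):
        v = np.column_stack([np.ones(3), np.zeros(3)])
        with pytest.raises(ValueError, match="zero-norm"):
            merge_candidates(v, ["edema", "edema"])


class TestSPA:
    def test_scaled_canonical_basis_selects_largest_norms(self):
        # brute-force oracle: with orthogonal columns, cumulative deflation
        # never changes other columns, so picks are simply by norm order
        scales = np.array([3.0, 1.0, 7.0, 5.0, 2.0])
        X = np.diag(scales)
        picked = spa_select(X, None, k=3)
        assert picked == [2, 3, 0]

    def test_first_pick_is_argmax_of_projected_norms(self, rng):
        X = rng.uniform(size=(6, 25))
        P = rng.uniform(size=(6, 2))
        picked = spa_select(X, P, k=1)
        Q, _ = np.linalg.qr(P)
        resid = X - Q @ (Q.T @ X)
        assert picked[0] == int(np.argmax(np.sum(resid * resid, axis=0)))

    def test_columns_in_pathological_span_never_selected(self, rng):
        P = rng.uniform(0.1, 1.0, size=(8, 2))
        spanned = P @ rng.uniform(size=(2, 4))  # 4 columns inside span(P)
        free = rng.uniform(size=(8, 6))
        X = np.column_stack([spanned, free])
        picked = spa_select(X, P, k=4)
        assert all(j >= 4 for j in picked)

    def test_rank_collapse_raises(self):
        X = np.ones((3, 5))  # rank one: second pick impossible
        with pytest.raises(ValueError, match="rank collapse"):
            spa_select(X, None, k=2)


class TestFCM:
    def test_exact_clusters_are_a_fixed_point(self):
        pts = np.array([[0.0, 1.0], [0.0, 1.0]])
        X = np.repeat(pts, [10, 10], axis=1)
        C = fcm_refine(X, np.empty((2, 0)), pts.copy())
        assert np.allclose(C, pts, atol=1e-8)

    def test_pathological_centroids_bit_identical(self, rng):
        X = rng.uniform(size=(4, 60))
        path = rng.uniform(size=(4, 2))
        normal = rng.uniform(size=(4, 3))
        C = fcm_refine(X, path, normal)
        assert np.array_equal(C[:, :2], path)

    def test_two_blob_centroid_recovery(self, rng):
        mu1, mu2 = np.array([0.2, 0.3, 0.2]), np.array([0.8, 0.7, 0.9])
        pts = np.vstack(
            [rng.normal(mu1, 0.02, size=(150, 3)), rng.normal(mu2, 0.02, size=(150, 3))]
        ).T
        init = pts[:, [0, 299]]  # one sample from each blob
        C = fcm_refine(pts, np.empty((3, 0)), init)
        d1 = min(np.linalg.norm(C[:, 0] - mu1), np.linalg.norm(C[:, 1] - mu1))
        d2 = min(np.linalg.norm(C[:, 0] - mu2), np.linalg.norm(C[:, 1] - mu2))
        assert d1 < 0.05 and d2 < 0.05


class TestInitH:
    def test_exact_column_of_identity_w(self):
        W = np.eye(2)
        H = init_H(np.array([[3.0], [4.0]]), W)
        assert np.allclose(H[:, 0], [3.0, 4.0])

    def test_column_equal_to_source_gives_indicator(self, rng):
        W = np.linalg.qr(rng.uniform(size=(5, 3)))[0]  # orthonormal, mixed signs ok
        W = np.abs(W)
        W, _ = np.linalg.qr(W)
        W = np.abs(W)  # keep it simple: orthogonalish positive
        X = W[:, [1]]
        H = init_H(X, W)
        assert np.allclose(W @ H[:, 0], X[:, 0], atol=1e-8)

    def test_matches_exhaustive_support_enumeration(self, rng):
        W = rng.uniform(size=(5, 3))
        X = rng.uniform(-0.2, 1.0, size=(5, 20))
        H = init_H(X, W)
        for j in range(20):
            best = np.inf
            for k in range(4):
                for sup in itertools.combinations(range(3), k):
                    if not sup:
                        res = np.linalg.norm(X[:, j])
                    else:
                        sol, *_ = np.linalg.lstsq(W[:, sup], X[:, j], rcond=None)
                        if np.any(sol < -1e-12):
                            continue
                        res = np.linalg.norm(X[:, j] - W[:, sup] @ sol)
                    best = min(best, res)
            got = np.linalg.norm(X[:, j] - W @ H[:, j])
            assert got == pytest.approx(best, abs=1e-8)
            assert np.all(H[:, j] >= 0.0)
            assert got <= np.linalg.norm(X[:, j]) + 1e-12  # beats the zero vector


class TestResampling:
    def test_factor_one_is_identity(self, rng):
        fm = _grid_fm(rng, 6, 6)
        assert downsample_problem(fm, 1) is fm
        H = rng.uniform(size=(2, fm.n_voxels))
        assert upsample_abundances(H, fm, fm, 1) is H

    def test_constant_map_upsamples_to_constant(self, rng):
        fm = _grid_fm(rng, 9, 9)
        fmd = downsample_problem(fm, 2)
        H = np.full((1, fmd.n_voxels), 0.42)
        up = upsample_abundances(H, fmd, fm, 2)
        assert np.allclose(up, 0.42)

    def test_linear_ramp_reproduced_exactly(self):
        # bilinear interpolation is exact on in-plane linear fields when the
        # coarse grid brackets every fine position (odd extent)
        vi = np.array([(x, y, 0) for y in range(9) for x in range(9)])
        fm = _fm(np.ones((2, 81)), vi, (9, 9, 1))
        fmd = downsample_problem(fm, 2)
        vd = fmd.voxel_index
        H = (1.5 * vd[:, 0] + 0.5 * vd[:, 1] + 2.0)[None, :]
        up = upsample_abundances(H, fmd, fm, 2)
        want = 1.5 * vi[:, 0] + 0.5 * vi[:, 1] + 2.0
        assert np.allclose(up[0], want, atol=1e-12)

    def test_downsample_keeps_even_positions_only(self, rng):
        fm = _grid_fm(rng, 6, 6)
        fmd = downsample_problem(fm, 2)
        assert np.all(fmd.voxel_index[:, 0] % 2 == 0)
        assert np.all(fmd.voxel_index[:, 1] % 2 == 0)

    def test_seed_snapping_to_retained_grid(self, rng):
        fm = _grid_fm(rng, 6, 6)
        fmd = downsample_problem(fm, 2)
        seeds = SeedSet(seeds=[((3, 3, 0), "active_tumor")])
        snapped = snap_seeds(seeds, fmd)
        coord = snapped.seeds[0][0]
        assert coord in fmd.column_lookup()
        assert abs(coord[0] - 3) <= 1 and abs(coord[1] - 3) <= 1


class TestWholeInit:
    def test_deterministic_and_rank_contract(self, small_phantom):
        spec, data = small_phantom
        fm = build_feature_matrix(rescale_features(data.study))
        fmd = downsample_problem(fm, 2)
        seeds = snap_seeds(data.seeds, fmd)
        a = initialize(fmd, seeds)
        b = initialize(fmd, seeds)
        assert np.array_equal(a.W0, b.W0) and np.array_equal(a.H0, b.H0)
        assert a.source_labels == b.source_labels
        n_path = len(a.seed_provenance)
        assert a.rank == n_path + 8
        assert np.all(a.H0 >= 0.0) and np.all(a.W0 >= 0.0)
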
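"""Lattice fitting: centroids, anchor pairs, cost oracle, robustness."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

import cryotarget as ct
from cryotarget.lattice import (
    LatticeAnchorError,
    ProbabilityMap,
    rasterize_lattice,
)


class TestNormalize:
    def test_constant_image_all_zeros(self):
        out = ct.normalize_medium_mag(np.full((8, 8), 3.7))
        assert np.allclose(out, 0.0)

    def test_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        out = ct.normalize_medium_mag(rng.uniform(5, 9, (32, 32)))
        assert abs(out.mean()) < 1e-6
        assert abs(out.std() - 1) < 1e-6

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        img = rng.normal(0, 1, (16, 16))
        assert np.allclose(ct.normalize_medium_mag(3.2 * img + 7.0),
                           ct.normalize_medium_mag(img))


class TestCentroids:
    def test_plateau_centers(self):
        v = np.zeros((20, 20))
        v[2:5, 2:5] = 1.0
        v[10:13, 14:17] = 1.0
        cents = ct.extract_centroids(ProbabilityMap(values=v), 0.5)
        assert sorted(map(tuple, cents)) == [(3.0, 3.0), (11.0, 15.0)]

    def test_gaussian_bump_weighted_mean_oracle(self):
        rr, cc = np.mgrid[0:31, 0:31].astype(float)
        v = np.exp(-((rr - 14.3) ** 2 + (cc - 17.8) ** 2) / (2 * 3.0 ** 2))
        pmap = ProbabilityMap(values=v)
        (cy, cx), = ct.extract_centroids(pmap, 0.5)
        # oracle: probability-weighted mean over the thresholded region
        mask = v >= 0.5
        ey = (rr * v)[mask].sum() / v[mask].sum()
        ex = (cc * v)[mask].sum() / v[mask].sum()
        assert (cy, cx) == pytest.approx((ey, ex))
        assert (cy, cx) == pytest.approx((14.3, 17.8), abs=0.5)

    def test_threshold_above_max_empty(self):
        v = np.full((10, 10), 0.3)
        assert len(ct.extract_centroids(ProbabilityMap(values=v), 0.9)) == 0


class TestCandidatePairs:
    def test_three_centroids_all_pairs(self):
        cents = np.array([[0, 0], [0, 5], [4, 2]], float)
        pairs = ct.candidate_pairs(cents, k_neighbors=6)
        assert len(pairs) == 3  # K exceeds available -> all unordered pairs

    def test_grid_k1_pairs_at_pitch(self):
        pts = np.array([[r, c] for r in (0, 10, 20) for c in (0, 10, 20)], float)
        pairs = ct.candidate_pairs(pts, k_neighbors=1)
        for a, b in pairs:
            assert np.linalg.norm(b - a) == pytest.approx(10.0)

    def test_pair_count_bound(self):
        rng = np.random.default_rng(2)
        cents = rng.uniform(0, 100, (17, 2))
        pairs = ct.candidate_pairs(cents, k_neighbors=4)
        assert len(pairs) <= 17 * 4

    def test_fewer_than_two_centroids_error(self):
        with pytest.raises(LatticeAnchorError):
            ct.candidate_pairs(np.array([[1.0, 1.0]]), 6)


class TestGenerateLattice:
    def test_enumeration_in_small_image(self):
        lat = ct.generate_lattice((0, 0), (0, 10), (20, 20))
        got = sorted(map(tuple, np.round(lat.points, 6)))
        assert got == [(0.0, 0.0), (0.0, 10.0), (10.0, 0.0), (10.0, 10.0)]

    def test_anchor_swap_symmetry(self):
        a = ct.generate_lattice((3, 4), (9, 12), (64, 64))
        b = ct.generate_lattice((9, 12), (3, 4), (64, 64))
        assert np.allclose(sorted(map(tuple, a.points)),
                           sorted(map(tuple, b.points)))

    def test_nearest_neighbour_distance_equals_pitch(self):
        lat = ct.generate_lattice((7, 5), (12, 17), (128, 128))
        pitch = np.hypot(5, 12)
        tree = cKDTree(lat.points)
        d, _ = tree.query(lat.points, k=2)
        interior = (lat.points > pitch).all(axis=1) & \
                   (lat.points < 128 - pitch).all(axis=1)
        assert np.allclose(d[interior, 1], pitch, atol=1e-9)

    def test_coincident_anchors_rejected(self):
        with pytest.raises(ValueError):
            ct.generate_lattice((5, 5), (5, 5), (32, 32))

    def test_overlapping_holes_rejected(self):
        with pytest.raises(ValueError):
            ct.generate_lattice((0, 0), (0, 4), (32, 32), render_radius=3.0)

    def test_basis_orthogonal_equal_length(self):
        lat = ct.generate_lattice((1, 2), (5, 9), (64, 64))
        v, w = lat.basis
        assert np.dot(v, w) == pytest.approx(0.0)
        assert np.linalg.norm(v) == pytest.approx(np.linalg.norm(w))


class TestLatticeCost:
    def test_perfect_match_zero_cost(self):
        lat = ct.generate_lattice((8, 8), (8, 24), (64, 64))
        cfg = ct.LatticeFitConfig(render_radius=4.0)
        L = rasterize_lattice(lat, (64, 64), 4.0)
        cost = ct.lattice_cost(ProbabilityMap(values=L.astype(float)), lat, cfg)
        assert cost == 0.0

    def test_closed_form_all_zero_map(self):
        # O = 0 everywhere: cost = lambda1 * covered fraction
        lat = ct.generate_lattice((8, 8), (8, 24), (64, 64))
        cfg = ct.LatticeFitConfig(lambda_fp=2.0, lambda_fn=1.0, render_radius=4.0)
        f = rasterize_lattice(lat, (64, 64), 4.0).mean()
        cost = ct.lattice_cost(ProbabilityMap(values=np.zeros((64, 64))), lat, cfg)
        assert cost == pytest.approx(2.0 * f)

    def test_matches_brute_force_pixel_sum(self):
        rng = np.random.default_rng(3)
        O = rng.uniform(0, 1, (48, 48))
        lat = ct.generate_lattice((5, 6), (5, 18), (48, 48))
        cfg = ct.LatticeFitConfig(lambda_fp=1.3, lambda_fn=2.7, render_radius=3.0)
        cost = ct.lattice_cost(ProbabilityMap(values=O), lat, cfg)
        # oracle: per-pixel double loop
        L = np.zeros((48, 48))
        for r in range(48):
            for c in range(48):
                d2 = ((lat.points[:, 0] - r) ** 2 + (lat.points[:, 1] - c) ** 2)
                L[r, c] = 1.0 if (d2 <= 9.0).any() else 0.0
        expected = (1.3 * L * (1 - O) + 2.7 * (1 - L) * O).sum() / O.size
        assert cost == pytest.approx(expected, abs=1e-9)


class TestFitLattice:
    def test_true_pair_recovers_map(self, hole_scene, clean_probability_map):
        cfg = ct.LatticeFitConfig()
        lat = ct.fit_lattice(clean_probability_map, cfg)
        assert lat.pitch == pytest.approx(32.0, rel=0.02)
        d, _ = cKDTree(lat.points).query(hole_scene.true_centers)
        assert (d <= 0.25 * 32).all()

    def test_full_k_equals_exhaustive_search(self):
        # K = n - 1 must agree exactly with brute-force all-pairs search
        spec = ct.HoleSceneSpec(96, 96, lattice_pitch_px=32, hole_radius_px=8,
                                lattice_origin_px=(16, 16),
                                dropout_fraction=0.3, seed=12)
        scene = ct.generate_hole_scene(spec)
        pmap = ct.generate_probability_map(scene, 3.0, n_spurious=2, seed=13)
        cfg = ct.LatticeFitConfig(k_neighbors=10 ** 6)
        cents = ct.extract_centroids(pmap, cfg.region_threshold)
        assert len(cents) <= 12
        lat = ct.fit_lattice(pmap, cfg)
        # oracle: exhaustive all-pairs minimum under the same admissibility
        from cryotarget.lattice import derive_min_pitch

        min_pitch = derive_min_pitch(pmap, cfg.region_threshold)
        best = None
        for i in range(len(cents)):
            for j in range(len(cents)):
                if i == j:
                    continue
                if np.linalg.norm(cents[j] - cents[i]) < min_pitch:
                    continue
                cand = ct.generate_lattice(cents[i], cents[j], pmap.values.shape)
                c = ct.lattice_cost(pmap, cand, cfg)
                if best is None or c < best[0] - 1e-12:
                    best = (c, cand)
        assert lat.cost == pytest.approx(best[0], abs=1e-12)
        assert np.allclose(sorted(map(tuple, lat.points)),
                           sorted(map(tuple, best[1].points)))

    def test_robust_to_dropout_and_spurious(self):
        # 30% dropout, 5 spurious blobs: fitted lattice covers >= 99% of
        # true centers and beats raw centroids on matching recall
        n_cov, n_tot = 0, 0
        for seed in range(5):
            spec = ct.HoleSceneSpec(128, 128, 32, 8, (16 + seed, 12 + seed),
                                    dropout_fraction=0.3, seed=20 + seed)
            scene = ct.generate_hole_scene(spec)
            pmap = ct.generate_probability_map(scene, 3.0, n_spurious=5,
                                               seed=30 + seed)
            lat = ct.fit_lattice(pmap, ct.LatticeFitConfig())
            d, _ = cKDTree(lat.points).query(scene.true_centers)
            n_cov += (d <= 0.25 * 32).sum()
            n_tot += len(scene.true_centers)

            gt = ct.GroundTruthHoles(scene.true_centers, 8.0)
            cents = ct.extract_centroids(pmap, 0.5)
            rec_lat = ct.match_predictions(lat.points, gt).recall
            rec_cen = ct.match_predictions(cents, gt).recall
            assert rec_lat >= rec_cen
        assert n_cov / n_tot >= 0.99

    def test_anchor_error_propagates(self):
        v = np.zeros((32, 32))
        v[5, 5] = 1.0
        with pytest.raises(LatticeAnchorError):
            ct.fit_lattice(ProbabilityMap(values=v), ct.LatticeFitConfig())


class TestScoreAndCrop:
    def test_uniform_map_score_is_area_times_p(self):
        lat = ct.generate_lattice((16, 16), (16, 48), (128, 128))
        pmap = ProbabilityMap(values=np.full((128, 128), 0.25))
        img = np.zeros((128, 128))
        crops = ct.score_and_crop(pmap, img, lat, ct.LatticeFitConfig())
        interior = [c for c in crops if c.pixels.shape == (32, 32)]
        assert interior
        for c in interior:
            assert c.unet_score == pytest.approx(32 * 32 * 0.25)

    def test_infinite_threshold_drops_everything(self):
        lat = ct.generate_lattice((16, 16), (16, 48), (128, 128))
        pmap = ProbabilityMap(values=np.full((128, 128), 0.5))
        cfg = ct.LatticeFitConfig(tile_prob_threshold=np.inf)
        assert ct.score_and_crop(pmap, np.zeros((128, 128)), lat, cfg) == []

    def test_percentile_threshold_retains_expected_fraction(self, hole_scene,
                                                            clean_probability_map):
        cfg = ct.LatticeFitConfig()
        lat = ct.fit_lattice(clean_probability_map, cfg)
        crops = ct.score_and_crop(clean_probability_map, hole_scene.image,
                                  lat, cfg)
        scores = np.array([c.unet_score for c in crops])
        cut = np.percentile(scores, 25)
        cfg2 = ct.LatticeFitConfig(tile_prob_threshold=cut)
        kept = ct.score_and_crop(clean_probability_map, hole_scene.image,
                                 lat, cfg2)
        expected = (scores >= cut).sum()
        assert abs(len(kept) - expected) <= 1
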
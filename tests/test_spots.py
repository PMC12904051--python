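"""Spot detection, subpixel localization, per-cell counting, round stability."""

import numpy as np
import pandas as pd
import pytest

from corrtaste.errors import GeometryError, ParameterError
from corrtaste.spots import (
    Spot,
    SpotCallParams,
    count_spots_per_cell,
    detect_spots,
    merge_spots_across_planes,
    spot_count_stability,
)
from corrtaste.synthetic import generate_scene, render_histology_rounds


def _gaussian_image(shape, centers, amplitude=1.0, sigma=1.5, noise=0.0, seed=0):
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    img = np.zeros(shape, float)
    amps = np.broadcast_to(np.asarray(amplitude, float), (len(centers),))
    for (x, y), a in zip(centers, amps):
        img += a * np.exp(-((xs - x) ** 2 + (ys - y) ** 2) / (2 * sigma**2))
    if noise:
        img += np.random.default_rng(seed).normal(0, noise, shape)
    return img


class TestDetectSpots:
    def test_blank_image_yields_empty_list(self):
        assert detect_spots(np.zeros((64, 64))) == []

    def test_subpixel_center_matches_grid_search_oracle(self):
        truth = (10.3, 7.6)
        img = _gaussian_image((32, 32), [truth], amplitude=1.0, sigma=1.5, noise=0.002)
        spots = detect_spots(img, SpotCallParams(threshold=0.1))
        assert len(spots) == 1
        s = spots[0]
        assert np.hypot(s.x - truth[0], s.y - truth[1]) < 0.2

        # independent oracle: dense grid search over subpixel centers
        ys, xs = np.mgrid[0:32, 0:32]
        best, best_c = np.inf, None
        for gx in np.arange(truth[0] - 1, truth[0] + 1, 0.05):
            for gy in np.arange(truth[1] - 1, truth[1] + 1, 0.05):
                model = np.exp(-((xs - gx) ** 2 + (ys - gy) ** 2) / (2 * 1.5**2))
                a = float((model * img).sum() / (model * model).sum())
                sse = float(((img - a * model) ** 2).sum())
                if sse < best:
                    best, best_c = sse, (gx, gy)
        assert np.hypot(s.x - best_c[0], s.y - best_c[1]) < 0.2

    def test_close_pair_keeps_brighter_maximum(self):
        img = _gaussian_image((48, 48), [(20.0, 20.0)], amplitude=1.0)
        img += _gaussian_image((48, 48), [(24.0, 20.0)], amplitude=0.6)
        spots = detect_spots(img, SpotCallParams(threshold=0.05, min_separation_px=5.0))
        assert len(spots) == 1
        assert abs(spots[0].x - 20.0) < 1.0  # the brighter of the two

    def test_well_separated_pair_both_found(self):
        img = _gaussian_image((48, 48), [(15.0, 15.0), (32.0, 30.0)], amplitude=1.0)
        spots = detect_spots(img, SpotCallParams(threshold=0.05))
        assert len(spots) == 2

    def test_translation_equivariance(self):
        centers = [(12.0, 14.0), (30.0, 22.0), (20.0, 34.0)]
        img = _gaussian_image((48, 48), centers, amplitude=1.0, noise=0.005)
        params = SpotCallParams(threshold=0.1)
        a = detect_spots(img, params)
        b = detect_spots(np.roll(img, (3, 5), axis=(0, 1)), params)
        pa = sorted((s.x, s.y) for s in a)
        pb = sorted((s.x - 5, s.y - 3) for s in b)
        assert np.allclose(pa, pb, atol=1e-6)

    def test_auto_threshold_rejects_pure_noise(self):
        img = np.random.default_rng(8).normal(0, 0.01, (96, 96))
        assert len(detect_spots(img)) <= 2

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            SpotCallParams(dog_sigma_small=3.0, dog_sigma_large=1.0)
        with pytest.raises(ParameterError):
            SpotCallParams(min_separation_px=0.0)

    @pytest.mark.parametrize("amp_factor,noise", [(2, 0.01), (8, 0.03), (20, 0.05)])
    def test_precision_recall_on_separated_fields(self, amp_factor, noise):
        rng = np.random.default_rng(amp_factor)
        # dart-throwing placement with > 6 px separation
        centers = []
        while len(centers) < 40:
            c = rng.uniform(6, 122, 2)
            if all(np.hypot(c[0] - x, c[1] - y) > 6.5 for x, y in centers):
                centers.append(tuple(c))
        base_amp = noise * 5 * 1.4826  # roughly the auto threshold scale
        img = _gaussian_image((128, 128), centers, amplitude=amp_factor * base_amp,
                              noise=noise, seed=amp_factor)
        spots = detect_spots(img)
        matched = 0
        for x, y in centers:
            if any(np.hypot(s.x - x, s.y - y) < 2.0 for s in spots):
                matched += 1
        recall = matched / len(centers)
        precision = (
            sum(any(np.hypot(s.x - x, s.y - y) < 2.0 for x, y in centers) for s in spots)
            / max(len(spots), 1)
        )
        assert recall >= 0.95
        assert precision >= 0.95


class TestMergeAcrossPlanes:
    def test_adjacent_plane_duplicates_collapse(self):
        spots = [
            Spot(10.0, 10.0, z_plane=0, gene="g", amplitude=5.0),
            Spot(10.5, 10.2, z_plane=1, gene="g", amplitude=3.0),
            Spot(10.4, 10.1, z_plane=2, gene="g", amplitude=2.0),
            Spot(30.0, 30.0, z_plane=1, gene="g", amplitude=4.0),
        ]
        merged = merge_spots_across_planes(spots)
        assert len(merged) == 2
        assert {round(s.x) for s in merged} == {10, 30}

    def test_different_genes_never_merge(self):
        spots = [
            Spot(10.0, 10.0, z_plane=0, gene="a", amplitude=5.0),
            Spot(10.0, 10.0, z_plane=1, gene="b", amplitude=3.0),
        ]
        assert len(merge_spots_across_planes(spots)) == 2


class TestCounting:
    def _mask(self):
        m = np.zeros((40, 40), dtype=np.int32)
        m[5:15, 5:15] = 1
        m[5:15, 22:32] = 3
        return m

    def test_no_spots_gives_zero_rows_for_every_label(self):
        counts = count_spots_per_cell([], self._mask())
        assert list(counts.index) == [1, 3]
        assert counts.empty or (counts.to_numpy() == 0).all()

    def test_interior_and_boundary_assignment(self):
        mask = self._mask()
        spots = [
            Spot(10.0, 10.0, gene="g"),  # inside label 1
            Spot(20.5, 10.0, gene="g"),  # 1 px outside label 3 (starts at x=22)... adjust
        ]
        # boundary spot exactly 1 px outside label 3, radius 2 -> assigned to 3
        spots[1] = Spot(21.0, 10.0, gene="g")
        counts = count_spots_per_cell(spots, mask, assign_radius_px=2.0)
        assert counts.loc[1, "g"] == 1
        assert counts.loc[3, "g"] == 1
        assert spots[1].cell_label == 3

    def test_far_background_spot_stays_unassigned(self):
        mask = self._mask()
        spots = [Spot(18.0, 35.0, gene="g")]
        counts = count_spots_per_cell(spots, mask, assign_radius_px=2.0)
        assert spots[0].cell_label == 0
        assert counts["g"].sum() == 0

    def test_equidistant_tie_is_unassigned(self):
        mask = self._mask()
        # x = 18.0 is exactly 4.0 px from label 1 (ends at 14) and label 3 (starts at 22)
        spots = [Spot(18.0, 10.0, gene="g")]
        count_spots_per_cell(spots, mask, assign_radius_px=5.0)
        assert spots[0].cell_label == 0

    def test_nearest_of_two_wins(self):
        mask = self._mask()
        spots = [Spot(17.0, 10.0, gene="g")]  # 2.5 px from label 1, 5.5 from label 3
        count_spots_per_cell(spots, mask, assign_radius_px=6.0)
        assert spots[0].cell_label == 1

    def test_conservation_assigned_plus_unassigned(self):
        rng = np.random.default_rng(4)
        mask = self._mask()
        spots = [Spot(float(x), float(y), gene="g") for x, y in rng.uniform(0, 39, (50, 2))]
        counts = count_spots_per_cell(spots, mask, assign_radius_px=2.0)
        n_assigned = sum(s.cell_label > 0 for s in spots)
        assert counts["g"].sum() == n_assigned
        assert n_assigned + sum(s.cell_label == 0 for s in spots) == 50

    def test_out_of_frame_spot_is_geometry_error(self):
        with pytest.raises(GeometryError):
            count_spots_per_cell([Spot(99.0, 2.0, gene="g")], self._mask())

    def test_counts_recover_truth_for_separated_cells(self):
        # sparse expression so rendered spots respect the 5-px separation rule
        sc = generate_scene(
            8, seed=31, image_shape=(192, 192), bud_diameter_um=60,
            gene_count_params={"high_mean": 5.0, "neg_mean": 0.5},
        )
        rounds = render_histology_rounds(
            sc, n_rounds=1, seed=2, noise_sigma=0.01, fiducial_amplitude=0.0
        )
        for gene, img in rounds[0].payload.items():
            pts = sc.true_spot_positions[gene][:, :2]
            spots = detect_spots(img, SpotCallParams(threshold=0.1), gene=gene)
            counts = count_spots_per_cell(spots, sc.cell_labels, assign_radius_px=2.0)
            for lab in sc.labels:
                # only cells whose spots all respect the separation radius
                own = pts[sc.true_spot_positions[gene][:, 3] == lab]
                if len(own) == 0:
                    continue
                d = np.linalg.norm(pts[None, :, :] - own[:, None, :], axis=-1)
                nn = np.sort(np.where(d.T > 0, d.T, np.inf), axis=0)[0]
                if np.all(nn > 5.5):
                    assert counts.loc[lab, gene] == sc.true_counts.loc[lab, gene]


class TestStability:
    def test_identical_tables(self):
        a = pd.Series([5, 8, 2, 10], index=[1, 2, 3, 4])
        res = spot_count_stability(a, a.copy())
        assert res["slope"] == pytest.approx(1.0)
        assert (res["deltas"] == 0).all()
        assert res["wilcoxon_p"] == 1.0

    def test_halved_counts_give_half_slope(self):
        a = pd.Series([10, 20, 30, 40], index=[1, 2, 3, 4], dtype=float)
        res = spot_count_stability(a, 0.5 * a)
        assert res["slope"] == pytest.approx(0.5, abs=0.05)

    def test_poisson_resampling_keeps_unit_slope(self):
        slopes = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = pd.Series(rng.poisson(20, 30) + 1.0)
            b = pd.Series(rng.poisson(a.to_numpy()).astype(float))
            slopes.append(spot_count_stability(a, b)["slope"])
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.1)

    def test_disjoint_cells_rejected(self):
        with pytest.raises(ParameterError):
            spot_count_stability(
                pd.Series([1], index=[1]), pd.Series([1], index=[2])
            )
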
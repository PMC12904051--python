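"""Multimodal profile assembly and correlative statistics (ROC, classes, adjacency)."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from corrtaste.errors import (
    ConfigurationError,
    ConsistencyError,
    GeometryError,
    ParameterError,
)
from corrtaste.integrate import (
    afferent_adjacency,
    build_cell_profiles,
    call_expression_class,
    classify_if_positive,
    roc_curve,
    summarize_dual_tuning,
)
from corrtaste.synthetic import generate_scene


def _mask_two_cells():
    m = np.zeros((40, 40), dtype=np.int32)
    m[5:15, 5:15] = 1
    m[25:35, 25:35] = 2
    return m


class TestBuildProfiles:
    def test_single_sour_cell_carries_all_modalities(self):
        mask = np.zeros((20, 20), dtype=np.int32)
        mask[5:15, 5:15] = 1
        counts = {1: pd.DataFrame({"CA4": [20]}, index=pd.Index([1], name="cell"))}
        if_tab = {
            "CA4": pd.DataFrame(
                {"if_intensity": [0.8], "if_positive": [True]},
                index=pd.Index([1], name="cell"),
            )
        }
        resp = pd.DataFrame({"mean_z_sour": [3.0], "responsive_sour": [True]},
                            index=pd.Index([1], name="roi_id"))
        prof = build_cell_profiles(mask, counts, if_tab, resp)
        assert prof.loc[1, "count_CA4"] == 20
        assert bool(prof.loc[1, "if_CA4"])
        assert prof.loc[1, "mean_z_sour"] == 3.0

    def test_missing_modality_is_null_not_zero(self):
        prof = build_cell_profiles(_mask_two_cells(), {1: pd.DataFrame(
            {"CA4": [4]}, index=pd.Index([1], name="cell"))})
        assert prof.loc[1, "count_CA4"] == 4
        assert pd.isna(prof.loc[2, "count_CA4"])

    def test_row_count_equals_label_count(self):
        prof = build_cell_profiles(_mask_two_cells())
        assert len(prof) == 2

    def test_earliest_round_wins_for_reprobed_gene(self):
        idx = pd.Index([1, 2], name="cell")
        counts = {
            1: pd.DataFrame({"Tas1R3": [10, 12]}, index=idx),
            4: pd.DataFrame({"Tas1R3": [7, 9]}, index=idx),
        }
        prof = build_cell_profiles(_mask_two_cells(), counts)
        assert prof.loc[1, "count_Tas1R3"] == 10

    def test_unknown_label_is_consistency_error(self):
        counts = {1: pd.DataFrame({"CA4": [1]}, index=pd.Index([9], name="cell"))}
        with pytest.raises(ConsistencyError):
            build_cell_profiles(_mask_two_cells(), counts)


class TestIfPositive:
    def test_bimodal_split(self):
        calls = classify_if_positive(np.array([1.0, 1.0, 1.0, 10.0, 11.0]))
        assert list(calls) == [False, False, False, True, True]

    def test_manual_threshold(self):
        calls = classify_if_positive(np.array([0.1, 0.2, 0.3, 0.4]), method=1.0)
        assert not calls.any()

    def test_otsu_is_scale_invariant(self):
        vals = np.array([0.5, 0.6, 0.4, 5.0, 6.0, 0.55])
        assert (classify_if_positive(vals) == classify_if_positive(2.0 * vals)).all()

    def test_too_few_cells_rejected(self):
        with pytest.raises(ParameterError):
            classify_if_positive(np.array([1.0, 2.0]))

    def test_constant_intensities_rejected(self):
        with pytest.raises(ParameterError):
            classify_if_positive(np.ones(6))


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        labels = np.array([False, False, False, True, True, True])
        r = roc_curve(scores, labels)
        assert r.auc == pytest.approx(1.0)
        assert 3.0 < r.optimal_threshold <= 10.0

    def test_auc_equals_mann_whitney_identity(self):
        rng = np.random.default_rng(5)
        scores = np.round(rng.normal(0, 1, 60), 1)  # rounding forces ties
        labels = rng.uniform(size=60) < 0.4
        labels[0], labels[1] = True, False  # both classes non-empty
        r = roc_curve(scores, labels)
        u = stats.mannwhitneyu(scores[labels], scores[~labels]).statistic
        n1, n0 = labels.sum(), (~labels).sum()
        assert abs(r.auc - u / (n1 * n0)) < 1e-9

    def test_matches_sklearn_reference(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(6)
        scores = rng.normal(0, 1, 80) + rng.integers(0, 2, 80)
        labels = rng.uniform(size=80) < 0.5
        labels[:2] = [True, False]
        r = roc_curve(scores, labels)
        assert r.auc == pytest.approx(
            sklearn_metrics.roc_auc_score(labels, scores), abs=1e-9
        )

    def test_label_independent_feature_has_half_auc(self):
        aucs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            scores = rng.normal(0, 1, 40)
            labels = np.zeros(40, bool)
            labels[rng.permutation(40)[:20]] = True
            aucs.append(roc_curve(scores, labels).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_curve(np.arange(5.0), np.ones(5, bool))

    def test_synthetic_count_cohort_threshold_between_medians(self):
        # CA4 counts: high expressers vs negative cells from the count model
        rng = np.random.default_rng(17)
        pos = rng.negative_binomial(5, 5 / 30, 25).astype(float)
        neg = rng.poisson(1.0, 25).astype(float)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(25, bool), np.zeros(25, bool)])
        r = roc_curve(scores, labels)
        assert np.median(neg) < r.optimal_threshold < np.median(pos)
        assert r.auc >= 0.95


class TestExpressionClass:
    def _profiles(self, rows):
        df = pd.DataFrame(rows).set_index("cell")
        df.index.name = "cell"
        return df

    def test_control_percentile_and_dual_call(self):
        rows = [
            {"cell": 1, "count_Tas1R1": 0, "count_Tas1R2": 1, "count_Tas1R3": 2},
            {"cell": 2, "count_Tas1R1": 1, "count_Tas1R2": 2, "count_Tas1R3": 0},
            {"cell": 3, "count_Tas1R1": 2, "count_Tas1R2": 0, "count_Tas1R3": 1},
            {"cell": 4, "count_Tas1R1": 20, "count_Tas1R2": 18, "count_Tas1R3": 25},
        ]
        calls = call_expression_class(self._profiles(rows), control_cells=[1, 2, 3])
        assert calls[4] == "dual"
        assert all(calls[c] == "sour" for c in (1, 2, 3))

    def test_all_zero_counts_is_negative(self):
        rows = [
            {"cell": 1, "count_Tas1R1": 0, "count_Tas1R2": 0, "count_Tas1R3": 0},
        ]
        calls = call_expression_class(
            self._profiles(rows), fixed_thresholds={g: 3.0 for g in ("Tas1R1", "Tas1R2", "Tas1R3")}
        )
        assert calls[1] == "negative"

    def test_sweet_pattern_with_fixed_threshold(self):
        rows = [{"cell": 1, "count_Tas1R1": 0, "count_Tas1R2": 15, "count_Tas1R3": 20}]
        calls = call_expression_class(
            self._profiles(rows), fixed_thresholds={g: 3.0 for g in ("Tas1R1", "Tas1R2", "Tas1R3")}
        )
        assert calls[1] == "sweet"

    def test_umami_pattern(self):
        rows = [{"cell": 1, "count_Tas1R1": 12, "count_Tas1R2": 1, "count_Tas1R3": 20}]
        calls = call_expression_class(
            self._profiles(rows), fixed_thresholds={g: 3.0 for g in ("Tas1R1", "Tas1R2", "Tas1R3")}
        )
        assert calls[1] == "umami"

    def test_no_control_and_no_threshold_is_config_error(self):
        rows = [{"cell": 1, "count_Tas1R1": 1, "count_Tas1R2": 1, "count_Tas1R3": 1}]
        with pytest.raises(ConfigurationError):
            call_expression_class(self._profiles(rows))


class TestAdjacency:
    def test_overlapping_roi_finds_only_that_cell(self):
        mask = _mask_two_cells()
        roi = np.array([[7.0, 7.0], [12.0, 7.0], [12.0, 12.0], [7.0, 12.0]])
        adj = afferent_adjacency([roi], mask, radius_um=1.0, pixel_size_um=0.5)
        assert adj[0] == (1,)

    def test_equidistant_roi_finds_both_cells(self):
        mask = np.zeros((40, 40), dtype=np.int32)
        mask[10:20, 5:15] = 1
        mask[10:20, 25:35] = 2
        # centred between the two cells: 4 px to label 1 (ends 14), 4 px to label 2
        roi = np.array([[18.0, 14.0], [21.0, 14.0], [21.0, 16.0], [18.0, 16.0]])
        adj = afferent_adjacency([roi], mask, radius_um=2.5, pixel_size_um=0.5)
        assert adj[0] == (1, 2)

    def test_isolated_roi_is_empty(self):
        mask = _mask_two_cells()
        roi = np.array([[1.0, 36.0], [3.0, 36.0], [3.0, 38.0], [1.0, 38.0]])
        adj = afferent_adjacency([roi], mask, radius_um=1.0, pixel_size_um=0.5)
        assert adj[0] == ()

    def test_degenerate_roi_is_geometry_error(self):
        with pytest.raises(GeometryError):
            afferent_adjacency(
                [np.array([[5.0, 5.0], [5.0, 5.0], [5.0, 5.0]])],
                _mask_two_cells(),
            )

    def test_generator_nerves_touch_their_intended_cells(self, small_scene):
        adj = afferent_adjacency(
            small_scene.nerve_rois, small_scene.cell_labels,
            radius_um=2.0, pixel_size_um=small_scene.pixel_size_um,
        )
        for roi in small_scene.nerve_rois:
            assert set(adj[roi.nerve_id]) == set(roi.adjacent_cells)


class TestDualTuning:
    def _nerves(self, classes):
        return pd.DataFrame(
            {"tuning_class": classes},
            index=pd.Index([f"nerve_{i}" for i in range(len(classes))], name="roi_id"),
        )

    def test_intrinsic_takes_precedence(self):
        nerves = self._nerves(["dual"])
        adjacency = {0: (1, 2, 3)}
        classes = pd.Series({1: "dual", 2: "sweet", 3: "umami"})
        out = summarize_dual_tuning(nerves, adjacency, classes)
        assert out["per_nerve"].loc[0, "attribution"] == "intrinsic"

    def test_spillover_needs_sweet_and_umami(self):
        nerves = self._nerves(["dual", "dual"])
        adjacency = {0: (1, 2), 1: (1,)}
        classes = pd.Series({1: "sweet", 2: "umami"})
        out = summarize_dual_tuning(nerves, adjacency, classes)
        per = out["per_nerve"].set_index("nerve_id")["attribution"]
        assert per["nerve_0"] == "spillover"
        assert per["nerve_1"] == "unexplained"
        assert out["fractions"]["spillover"] == pytest.approx(0.5)

    def test_non_dual_nerves_are_ignored(self):
        nerves = self._nerves(["sweet", "umami"])
        out = summarize_dual_tuning(nerves, {}, pd.Series(dtype=object))
        assert out["n_dual_nerves"] == 0
        assert out["zero_denominator"]
        assert np.isnan(out["fractions"]["intrinsic"])

    def test_missing_adjacency_is_consistency_error(self):
        nerves = self._nerves(["dual"])
        with pytest.raises(ConsistencyError):
            summarize_dual_tuning(nerves, {}, pd.Series(dtype=object))

    def test_fractions_sum_to_one(self):
        nerves = self._nerves(["dual"] * 4)
        adjacency = {0: (1,), 1: (2, 3), 2: (), 3: (1,)}
        classes = pd.Series({1: "dual", 2: "sweet", 3: "umami"})
        out = summarize_dual_tuning(nerves, adjacency, classes)
        assert sum(out["fractions"].values()) == pytest.approx(1.0)

    def test_generator_cohort_attribution_recovered(self):
        # nerves placed by the generator with known intrinsic/spillover truth
        recovered, truth = [], []
        for seed in range(12):
            sc = generate_scene(
                12, seed=seed, image_shape=(192, 192), bud_diameter_um=55,
                n_nerves=6, nerve_spillover_fraction=0.3,
            )
            classes = pd.Series(
                {int(l): c for l, c in zip(sc.labels, sc.cell_class)}
            ).replace({"sour": "negative", "silent": "negative"})
            adjacency = afferent_adjacency(
                sc.nerve_rois, sc.cell_labels, radius_um=2.0,
                pixel_size_um=sc.pixel_size_um,
            )
            nerves = pd.DataFrame(
                {"tuning_class": [r.tuning_class for r in sc.nerve_rois]},
                index=pd.Index([f"nerve_{r.nerve_id}" for r in sc.nerve_rois], name="roi_id"),
            )
            out = summarize_dual_tuning(nerves, adjacency, classes)
            for _, row in out["per_nerve"].iterrows():
                recovered.append(row["attribution"])
            truth.extend(
                r.attribution_truth for r in sc.nerve_rois if r.tuning_class == "dual"
            )
        assert recovered == truth
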
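"""Importance tensor normalization, marginal views, ROI stats, grouping."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from tstms.classify import Dataset, train_ovo
from tstms.features import FEATURE_VECTOR_LENGTH, index_of
from tstms.importance import (
    ImportanceTensor,
    RoiSpec,
    default_rois,
    grouped_analysis,
    lfc_importance,
    pairwise_maps,
    permutation_importance_columns,
    roi_stats,
    spatial_maps,
    temporal_profile,
    wavelength_totals,
)

FAST = {"n_estimators": 8, "colsample_bytree": 1.0, "min_child_samples": 2}


def _wide_xy(informative, n=60, seed=0, scales=None):
    """Full-width matrix where only `informative` columns carry the label."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, FEATURE_VECTOR_LENGTH)).astype(np.float32)
    y = np.array(["A", "N"] * (n // 2))
    scales = scales or [2.0] * len(informative)
    for col, s in zip(informative, scales):
        X[:, col] += s * (y == "A")
    return X, y


def _tensor(values=None, f8=0.0):
    shape = (7, 5, 50, 35)
    if values is None:
        values = np.zeros(shape)
    total = values.sum() + f8
    return ImportanceTensor(values=values / total * 100 * (1 - 0)
                            if total else values, f8_value=f8 / total * 100
                            if total else f8)


class TestLfcImportance:
    def test_single_informative_column_dominates(self):
        col = index_of("F4", 2, 25, 17)
        X, y = _wide_xy([col], seed=1)
        model = train_ovo(X, y, hyperparams=FAST)
        it = lfc_importance(model)
        fi, rest = np.unravel_index(col, (7, 5 * 50 * 35))
        assert it.values.reshape(7, -1)[fi, rest] > 50.0

    def test_ignored_columns_get_zero(self):
        col = index_of("F2", 0, 10, 10)
        X, y = _wide_xy([col], seed=2)
        model = train_ovo(X, y, hyperparams=FAST)
        it = lfc_importance(model)
        # a far-away, uninformative pixel of another feature
        other = index_of("F7", 4, 40, 30)
        fi, rest = np.unravel_index(other, (7, 5 * 50 * 35))
        assert it.values.reshape(7, -1)[fi, rest] == pytest.approx(0.0, abs=0.5)

    def test_normalization_sums_to_100(self):
        X, y = _wide_xy([index_of("F3", 1, 20, 20)], seed=3)
        model = train_ovo(X, y, hyperparams=FAST)
        it = lfc_importance(model)
        assert it.values.sum() + it.f8_value == pytest.approx(100.0, abs=1e-6)

    def test_permutation_surrogate_agrees_with_native_gains(self):
        cols = [index_of("F2", 0, r, 10) for r in range(5, 13)]
        X, y = _wide_xy(cols, n=80, seed=4,
                        scales=[0.2, 0.5, 0.8, 1.2, 1.6, 2.0, 2.6, 3.2])
        model = train_ovo(X, y, hyperparams={"n_estimators": 25,
                                             "colsample_bytree": 1.0})
        from tstms.importance import _native_gains

        native = _native_gains(model)[cols]
        perm = permutation_importance_columns(
            model, X, y, [np.array([c]) for c in cols], seed=0
        )
        rho, _ = spearmanr(native, perm)
        assert rho >= 0.8


class TestViews:
    def test_delta_tensor_propagates_to_single_hotspot(self):
        values = np.zeros((7, 5, 50, 35))
        values[3, 2, 25, 17] = 100.0  # all mass on one F4 pixel
        it = ImportanceTensor(values=values, f8_value=0.0)
        view = spatial_maps(it)
        assert view["summary"][25, 17] > 0
        assert np.count_nonzero(view["summary"]) == 1
        assert view["percents"]["F4"] == 100.0

    def test_percents_plus_f8_total_100(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(size=(7, 5, 50, 35))
        raw *= 90.0 / raw.sum()
        it = ImportanceTensor(values=raw, f8_value=100.0 - raw.sum())
        view = spatial_maps(it)
        total = sum(view["percents"].values()) + view["f8_percent"]
        assert total == pytest.approx(100.0, abs=1e-6)
        assert view["spatial_total_percent"] == pytest.approx(
            100.0 - it.f8_value
        )

    def test_uniform_tensor_gives_flat_maps_and_equal_fifths(self):
        values = np.full((7, 5, 50, 35), 90.0 / (7 * 5 * 50 * 35))
        it = ImportanceTensor(values=values, f8_value=90.0 - values.sum() + 10.0)
        view = spatial_maps(it)
        assert np.ptp(view["summary"]) < 1e-9
        profile = temporal_profile(it)
        np.testing.assert_allclose(profile, profile[0])
        np.testing.assert_allclose(profile.sum(), 100.0 - it.f8_value)

    def test_mass_in_first_pulse_frame(self):
        values = np.zeros((7, 5, 50, 35))
        values[:, 0] = 95.0 / (7 * 50 * 35)
        it = ImportanceTensor(values=values * (95.0 / values.sum()),
                              f8_value=5.0)
        profile = temporal_profile(it)
        np.testing.assert_allclose(profile, [95.0, 0, 0, 0, 0], atol=1e-9)

    def test_wavelength_totals_include_f8(self):
        values = np.zeros((7, 5, 50, 35))
        values[0] = 60.0 / (5 * 50 * 35)
        it = ImportanceTensor(values=values * (60.0 / values.sum()),
                              f8_value=40.0)
        totals = wavelength_totals(it)
        assert totals["F1"] == pytest.approx(60.0)
        assert totals["F8"] == pytest.approx(40.0)

    def test_invalid_tensor_rejected(self):
        with pytest.raises(ValueError):
            ImportanceTensor(values=np.full((7, 5, 50, 35), 1.0), f8_value=0.0)
        with pytest.raises(ValueError):
            ImportanceTensor(values=np.zeros((7, 5, 50, 35)), f8_value=-1.0)


class TestPairwiseMaps:
    def test_five_classes_yield_ten_maps(self):
        rng = np.random.default_rng(5)
        n = 50
        X = rng.normal(size=(n, FEATURE_VECTOR_LENGTH)).astype(np.float32)
        y = np.repeat(list("ADFSN"), n // 5)
        for i, c in enumerate("ADFSN"):
            X[y == c, index_of("F2", 0, 5 + i, 5 + i)] += 3.0
        subjects = np.tile([f"S{i}" for i in range(5)], n // 5)
        ds = Dataset(X=X, y=y, subjects=subjects)
        maps = pairwise_maps(ds, hyperparams=FAST)
        assert len(maps) == 10
        for entry in maps.values():
            assert entry["summary"].shape == (50, 35)
            assert entry["spatiotemporal_percent"] + entry["f8_percent"] == \
                pytest.approx(100.0, abs=1e-6)

    def test_hr_only_pair_attributes_importance_to_f8(self):
        rng = np.random.default_rng(6)
        n = 40
        X = rng.normal(size=(n, FEATURE_VECTOR_LENGTH)).astype(np.float32)
        y = np.array(["A", "N"] * (n // 2))
        X[:, index_of("F8")] = np.where(y == "A", 1.6, 1.1) + \
            rng.normal(0, 0.02, n)
        subjects = np.repeat([f"S{i}" for i in range(4)], n // 4)
        ds = Dataset(X=X, y=y, subjects=subjects)
        maps = pairwise_maps(ds, hyperparams=FAST)
        assert maps[("A", "N")]["f8_percent"] > 50.0


class TestRoiStats:
    def test_constant_map_has_equal_means_and_high_p(self):
        rng = np.random.default_rng(0)
        fold_maps = [np.full((50, 35), 1.0) + rng.normal(0, 1e-6, (50, 35))
                     for _ in range(20)]
        stats = roi_stats(np.full((50, 35), 1.0), default_rois(), fold_maps,
                          n_boot=2000, seed=0)
        means = [v["mean"] for v in stats.values()]
        np.testing.assert_allclose(means, 1.0, atol=1e-6)
        assert all(v["p_value"] > 0.05 for v in stats.values())

    def test_cheek_hotspot_detected(self):
        rois = default_rois()
        hotspot = rois.mask("left_cheek") | rois.mask("right_cheek")
        rng = np.random.default_rng(1)
        fold_maps = [
            np.where(hotspot, 0.15, 0.05) + rng.normal(0, 0.005, (50, 35))
            for _ in range(20)
        ]
        mean_map = np.mean(fold_maps, axis=0)
        stats = roi_stats(mean_map, rois, fold_maps, n_boot=2000, seed=0)
        assert stats["left_cheek"]["mean"] > stats["left_cheek"]["rest_mean"]
        assert stats["left_cheek"]["p_value"] < 0.05
        assert stats["forehead"]["mean"] < stats["left_cheek"]["mean"]

    def test_single_pixel_roi(self):
        rois = RoiSpec(regions={"pix": (10, 10, 11, 11)})
        fold_maps = [np.arange(50 * 35, dtype=float).reshape(50, 35)] * 3
        stats = roi_stats(fold_maps[0], rois, fold_maps, n_boot=100, seed=0)
        assert stats["pix"]["mean"] == fold_maps[0][10, 10]

    def test_invalid_roi_specs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            RoiSpec(regions={"a": (0, 0, 10, 10), "b": (5, 5, 15, 15)})
        with pytest.raises(ValueError, match="outside"):
            RoiSpec(regions={"a": (0, 0, 60, 10)})
        with pytest.raises(ValueError, match="2 fold maps"):
            roi_stats(np.zeros((50, 35)), default_rois(),
                      [np.zeros((50, 35))])


class TestGroupedAnalysis:
    def test_group_specific_signal_recovered(self):
        rng = np.random.default_rng(7)
        n = 64
        X = rng.normal(size=(n, FEATURE_VECTOR_LENGTH)).astype(np.float32)
        y = np.array(["A", "N"] * (n // 2))
        gender = np.repeat(["F", "M"], n // 2)
        subjects = np.concatenate([
            np.repeat(["S0", "S1"], n // 4), np.repeat(["S2", "S3"], n // 4)
        ])
        col = index_of("F4", 0, 8, 17)  # forehead pixel
        female = gender == "F"
        X[female & (y == "A"), col] += 3.0
        other = index_of("F4", 0, 40, 17)
        X[~female & (y == "A"), other] += 3.0
        ds = Dataset(X=X, y=y, subjects=subjects, gender=gender)
        out = grouped_analysis(ds, "gender", hyperparams=FAST)
        assert set(out) == {"F", "M"}
        assert out["F"]["maps"]["F4"][8, 17] > out["M"]["maps"]["F4"][8, 17]

    def test_unknown_key_rejected(self, tiny_cohort_dataset):
        ds, _ = tiny_cohort_dataset
        with pytest.raises(ValueError):
            grouped_analysis(ds, "age")


def test_chin_rows_receive_zero_importance(tiny_cohort_dataset):
    """Chin-masked pixels are constant-zero columns, hence zero importance."""
    ds, _ = tiny_cohort_dataset
    model = train_ovo(ds.X, ds.y, hyperparams=FAST)
    it = lfc_importance(model)
    assert np.all(it.values[:, :, -6:, :] == 0.0)
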
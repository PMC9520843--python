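"""Enrichment classification, co-positivity screening and line profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from endovesiq import (ClassificationParams, DetectionParams, FieldOfView,
                       LabeledMask, classify_field, classify_positive,
                       line_profile, measure_channel, screen_copositive,
                       detect_vesicles)
from endovesiq.colocalization import copositivity_column


def _mask_from(labels: np.ndarray) -> LabeledMask:
    return LabeledMask(labels=labels, detection_channel="cav1",
                       params=DetectionParams())


class TestMeasureChannel:
    def test_constant_raster(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[1, 1] = 1
        labels[3, 3:5] = 2
        means, ref = measure_channel(_mask_from(labels), np.full((5, 5), 7.0))
        assert np.allclose(means, [7.0, 7.0])
        assert ref == 7.0

    def test_two_pixel_vesicle_mean(self):
        labels = np.zeros((5, 5), dtype=int)
        labels[2, 2] = 1
        labels[2, 3] = 1
        raster = np.zeros((5, 5))
        raster[2, 2] = 10.0
        raster[2, 3] = 20.0
        means, ref = measure_channel(_mask_from(labels), raster)
        assert means[0] == 15.0
        assert ref == pytest.approx(30.0 / 25.0)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError):
            measure_channel(_mask_from(np.zeros((4, 4), dtype=int)),
                            np.zeros((5, 5)))

    def test_matches_bruteforce_accumulation(self, rng):
        labels = rng.integers(0, 6, size=(32, 32))
        raster = rng.uniform(0, 1000, size=(32, 32))
        means, _ = measure_channel(_mask_from(labels), raster)
        for k in range(1, labels.max() + 1):
            acc, n = 0.0, 0
            for r in range(32):
                for c in range(32):
                    if labels[r, c] == k:
                        acc += raster[r, c]
                        n += 1
            assert means[k - 1] == pytest.approx(acc / n, rel=1e-9)

    def test_reference_scopes(self, rng):
        labels = np.zeros((8, 8), dtype=int)
        labels[0:2, 0:2] = 1
        raster = rng.uniform(1, 10, size=(8, 8))
        _, full = measure_channel(_mask_from(labels), raster, "image_mean")
        _, outside = measure_channel(_mask_from(labels), raster, "outside_mean")
        _, median = measure_channel(_mask_from(labels), raster, "image_median")
        assert full == pytest.approx(raster.mean())
        assert outside == pytest.approx(raster[labels == 0].mean())
        assert median == pytest.approx(np.median(raster))


class TestClassifyPositive:
    def test_boundary_is_inclusive(self):
        flags, ratios = classify_positive(np.array([115.0]), 100.0)
        assert flags[0]
        assert ratios[0] == pytest.approx(1.15)

    def test_strict_mode_excludes_boundary(self):
        params = ClassificationParams(strict=True)
        flags, _ = classify_positive(np.array([115.0, 115.0001]), 100.0, params)
        assert list(flags) == [False, True]

    def test_constant_image_vesicle_is_negative(self):
        flags, ratios = classify_positive(np.array([100.0]), 100.0)
        assert not flags[0]
        assert ratios[0] == 1.0

    @pytest.mark.parametrize("bad_mean", [0.0, -5.0])
    def test_degenerate_reference_errors(self, bad_mean):
        with pytest.raises(ValueError, match="reference"):
            classify_positive(np.array([10.0]), bad_mean)

    @given(st.floats(min_value=1e-3, max_value=1e6))
    def test_scale_invariance(self, c):
        """Multiplying the raster by c > 0 changes no ratio and no flag."""
        means = np.array([80.0, 100.0, 114.9, 115.0, 300.0])
        f1, r1 = classify_positive(means, 100.0)
        f2, r2 = classify_positive(means * c, 100.0 * c)
        assert np.array_equal(f1, f2)
        assert np.allclose(r1, r2)

    @given(st.lists(st.floats(min_value=0, max_value=1e4), min_size=1,
                    max_size=30),
           st.floats(min_value=0, max_value=1.0),
           st.floats(min_value=0, max_value=1.0))
    def test_monotonicity_in_f(self, means, fa, fb):
        """The positive set at larger f is a subset of the set at smaller f."""
        lo, hi = sorted([fa, fb])
        means = np.asarray(means)
        flo, _ = classify_positive(means, 50.0, ClassificationParams(
            enrichment_fraction=lo))
        fhi, _ = classify_positive(means, 50.0, ClassificationParams(
            enrichment_fraction=hi))
        assert not np.any(fhi & ~flo)

    def test_f_zero_reduces_to_mean_comparison(self):
        means = np.array([99.9, 100.0, 100.1])
        flags, _ = classify_positive(means, 100.0, ClassificationParams(
            enrichment_fraction=0.0))
        assert list(flags) == [False, True, True]


class TestScreening:
    @pytest.fixture()
    def classified(self, small_field):
        fov, _ = small_field
        mask, table = detect_vesicles(fov, "cav1")
        table = classify_field(fov, mask, table, ["endoglin"])
        return fov, mask, table

    def test_base_negative_vesicles_are_false_not_missing(self, classified):
        fov, mask, table = classified
        out = screen_copositive(fov, mask, table, ["endoglin"], "smad1")
        col = copositivity_column(["endoglin"], "smad1")
        assert out[col].dtype == bool
        assert not out[col].isna().any()
        neg = ~out["pos_endoglin"]
        assert not out.loc[neg, col].any()

    def test_conjunction_bound(self, classified):
        """Co-positive count never exceeds any component positive count."""
        fov, mask, table = classified
        out = screen_copositive(fov, mask, table, ["endoglin"], "smad1")
        col = copositivity_column(["endoglin"], "smad1")
        n_co = out[col].sum()
        assert n_co <= out["pos_endoglin"].sum()
        assert n_co <= out["pos_smad1"].sum()
        assert np.array_equal(out[col],
                              out["pos_endoglin"] & out["pos_smad1"])

    def test_high_screen_ratio_makes_all_base_positive_copositive(self):
        labels = np.zeros((10, 10), dtype=int)
        labels[2, 2] = 1
        labels[7, 7] = 2
        mask = _mask_from(labels)
        chans = {
            "cav1": np.full((10, 10), 100.0),
            "endoglin": np.full((10, 10), 100.0),
            "smad1": np.full((10, 10), 100.0),
        }
        chans["endoglin"][2, 2] = 250.0   # vesicle 1 endoglin-positive
        chans["smad1"][2, 2] = 250.0      # screen ratio ~2 >= 1.15
        fov = FieldOfView(channels=chans)
        table = pd.DataFrame({"label": [1, 2]})
        table = classify_field(fov, mask, table, ["endoglin"])
        out = screen_copositive(fov, mask, table, ["endoglin"], "smad1")
        col = copositivity_column(["endoglin"], "smad1")
        assert list(out["pos_endoglin"]) == [True, False]
        assert list(out[col]) == [True, False]

    def test_unknown_screen_channel_errors(self, classified):
        fov, mask, table = classified
        with pytest.raises(KeyError):
            screen_copositive(fov, mask, table, ["endoglin"], "missing")

    def test_unclassified_base_marker_errors(self, small_field):
        fov, _ = small_field
        mask, table = detect_vesicles(fov, "cav1")
        with pytest.raises(ValueError):
            screen_copositive(fov, mask, table, ["endoglin"], "smad1")

    def test_per_marker_override_changes_screen_rule(self, classified):
        fov, mask, table = classified
        strictest = ClassificationParams(per_marker={
            "smad1": ClassificationParams(enrichment_fraction=10.0)})
        out = screen_copositive(fov, mask, table, ["endoglin"], "smad1",
                                strictest)
        col = copositivity_column(["endoglin"], "smad1")
        assert out[col].sum() == 0


class TestLineProfile:
    def test_constant_image_is_flat(self):
        fov = FieldOfView(channels={"cav1": np.full((32, 32), 42.0)})
        res = line_profile(fov, ["cav1"], (5, 5), (25, 25), n_samples=30)
        assert np.allclose(res.data["cav1"], 42.0)

    def test_sampling_contract(self):
        fov = FieldOfView(channels={"cav1": np.zeros((32, 32))},
                          pixel_size=0.2)
        res = line_profile(fov, ["cav1"], (0, 0), (0, 10), n_samples=50)
        pos = res.data["position_px"].to_numpy()
        assert len(pos) == 50
        assert pos[0] == 0.0
        assert pos[-1] == pytest.approx(10.0)
        assert np.all(np.diff(pos) > 0)
        assert res.data["position_um"].iloc[-1] == pytest.approx(2.0)

    def test_peak_at_blob_center(self):
        rr, cc = np.mgrid[0:64, 0:64]
        img = 10.0 + 100.0 * np.exp(-((rr - 30) ** 2 + (cc - 34) ** 2) / 8.0)
        fov = FieldOfView(channels={"cav1": img})
        res = line_profile(fov, ["cav1"], (30, 4), (30, 60), n_samples=57)
        peak_col = 4 + res.data["position_px"].iloc[
            int(res.data["cav1"].idxmax())]
        assert abs(peak_col - 34) <= 1.0

    def test_width_averages_parallel_lines(self):
        img = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 10))
        fov = FieldOfView(channels={"cav1": img})
        res = line_profile(fov, ["cav1"], (1, 1), (1, 8), width=3,
                           n_samples=8)
        assert np.allclose(res.data["cav1"], 2.0)

    @pytest.mark.parametrize("p0,p1", [((-1, 0), (5, 5)), ((0, 0), (40, 5)),
                                       ((3, 3), (3, 3))])
    def test_bad_segments_error(self, p0, p1):
        fov = FieldOfView(channels={"cav1": np.zeros((32, 32))})
        with pytest.raises(ValueError):
            line_profile(fov, ["cav1"], p0, p1)

    def test_n_samples_and_width_validation(self):
        fov = FieldOfView(channels={"cav1": np.zeros((16, 16))})
        with pytest.raises(ValueError):
            line_profile(fov, ["cav1"], (0, 0), (5, 5), n_samples=1)
        with pytest.raises(ValueError):
            line_profile(fov, ["cav1"], (0, 0), (5, 5), width=0)
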
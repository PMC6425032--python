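"""Adhesion/cup morphometry, phagocytosis scoring, group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phagokit import morphometry as mo
from phagokit import synthgen as sg


def _spot_image(shape, centres, sigma=2.0, amp=100.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.zeros(shape)
    for x0, y0 in centres:
        img += amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma ** 2))
    return img


class TestDetectAdhesions:
    def test_single_spot_centroid_within_one_pixel(self):
        img = _spot_image((120, 120), [(60, 55)])
        det = mo.detect_adhesions(img, pixel_size_um=0.1, max_sigma_um=0.4)
        assert len(det) == 1
        assert det["x_um"].iloc[0] == pytest.approx(6.0, abs=0.1)
        assert det["y_um"].iloc[0] == pytest.approx(5.5, abs=0.1)

    def test_blank_frame_no_detections(self):
        det = mo.detect_adhesions(np.zeros((64, 64)), pixel_size_um=0.1)
        assert len(det) == 0

    def test_two_spots_ten_pixels_apart(self):
        img = _spot_image((120, 120), [(50, 60), (60, 60)])
        det = mo.detect_adhesions(img, pixel_size_um=0.1, max_sigma_um=0.4)
        assert len(det) == 2

    def test_edge_adjacent_detection_excluded(self):
        img = _spot_image((120, 120), [(10, 10), (60, 60)])
        det = mo.detect_adhesions(img, pixel_size_um=0.1, max_sigma_um=0.4,
                                  window_um=4.0)
        assert len(det) == 1  # the corner spot's 4 um window leaves the frame


class TestAverageAdhesionWindows:
    def test_single_adhesion_average_is_that_window(self):
        img = _spot_image((120, 120), [(60, 60)])
        cents = pd.DataFrame({"x_um": [6.0], "y_um": [6.0]})
        m = mo.average_adhesion_windows(img, img, cents, pixel_size_um=0.1)
        assert m.n_adhesions == 1
        centre = m.actin.shape[0] // 2
        assert m.actin[centre, centre] == pytest.approx(100.0, rel=0.01)

    def test_identical_windows_average_to_one_window(self):
        img = _spot_image((200, 200), [(50, 50), (150, 150)])
        cents = pd.DataFrame({"x_um": [5.0, 15.0], "y_um": [5.0, 15.0]})
        m = mo.average_adhesion_windows(img, img, cents, pixel_size_um=0.1)
        single = mo.average_adhesion_windows(
            img, img, cents.iloc[:1], pixel_size_um=0.1)
        np.testing.assert_allclose(m.actin, single.actin, rtol=1e-9)

    def test_permutation_invariance(self):
        img = _spot_image((200, 200), [(50, 60), (140, 90), (90, 150)])
        cents = pd.DataFrame({"x_um": [5.0, 14.0, 9.0], "y_um": [6.0, 9.0, 15.0]})
        m1 = mo.average_adhesion_windows(img, img, cents, pixel_size_um=0.1)
        m2 = mo.average_adhesion_windows(img, img, cents.iloc[::-1], pixel_size_um=0.1)
        np.testing.assert_allclose(m1.actin, m2.actin, rtol=1e-12)

    def test_membrane_lifting_shows_annular_dip(self):
        """Averaged membrane radial profile dips at the programmed annulus
        radius around adhesions (the membrane-lifting signature)."""
        cfg = sg.SynthConfig(seed=9, image_shape=(256, 256))
        radii = sg.expanding_wave_radii(8.0, 0.8, 10, cfg.frame_interval_s)
        actin, membrane, truth = sg.gen_wave_movie(cfg, radii, n_adhesions=40,
                                                   membrane_dip_radius_um=0.5)
        cents = pd.DataFrame([{"x_um": x * cfg.pixel_size_um,
                               "y_um": y * cfg.pixel_size_um, "frame": 9}
                              for x, y, _ in truth.adhesion_centroids])
        m = mo.average_adhesion_windows(actin.data, membrane.data, cents,
                                        pixel_size_um=cfg.pixel_size_um)
        dip_r = m.radial_r_um[int(np.argmin(m.membrane_profile))]
        assert dip_r == pytest.approx(0.5, abs=0.15)
        # actin is brightest at the adhesion centre
        assert int(np.argmax(m.actin_profile)) == 0

    def test_no_centroids_rejected(self):
        with pytest.raises(ValueError):
            mo.average_adhesion_windows(np.zeros((50, 50)), np.zeros((50, 50)),
                                        pd.DataFrame(columns=["x_um", "y_um"]),
                                        pixel_size_um=0.1)


class TestMeasureAdhesions3d:
    def test_rendered_boxes_measured_exactly(self):
        vol, truth = sg.gen_adhesion_volume(sg.SynthConfig(seed=2),
                                            [1.0, 0.25], [0.3, 0.5])
        rec = mo.measure_adhesions_3d(vol, threshold=50.0)
        assert len(rec) == 2
        got = rec.sort_values("area_um2")[["area_um2", "height_um"]].to_numpy()
        want = truth.sort_values("area_um2")[["area_um2", "height_um"]].to_numpy()
        np.testing.assert_allclose(got, want, rtol=1e-9)

    def test_threshold_above_maximum_empty(self):
        vol, _ = sg.gen_adhesion_volume(sg.SynthConfig(seed=2), [1.0], [0.3])
        assert len(mo.measure_adhesions_3d(vol, threshold=1e6)) == 0


class TestMeasureCup:
    def test_uniform_roi(self):
        vol = np.full((4, 10, 10), 5.0)
        mask = np.zeros_like(vol, dtype=bool)
        mask[:1] = True  # 100 voxels
        res = mo.measure_cup(vol, mask)
        assert res.mean_intensity == 5.0
        assert res.integrated_intensity == 500.0
        assert res.n_voxels == 100

    def test_doubling_roi_doubles_integrated_not_mean(self):
        vol = np.full((4, 10, 10), 5.0)
        m1 = np.zeros_like(vol, dtype=bool)
        m1[:1] = True
        m2 = np.zeros_like(vol, dtype=bool)
        m2[:2] = True
        r1, r2 = mo.measure_cup(vol, m1), mo.measure_cup(vol, m2)
        assert r2.integrated_intensity == 2 * r1.integrated_intensity
        assert r2.mean_intensity == r1.mean_intensity

    def test_two_level_roi_volume_weighted_mean(self):
        vol = np.concatenate([np.full((1, 5, 5), 2.0), np.full((3, 5, 5), 10.0)])
        mask = np.ones_like(vol, dtype=bool)
        res = mo.measure_cup(vol, mask)
        assert res.mean_intensity == pytest.approx((2.0 * 25 + 10.0 * 75) / 100)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mo.measure_cup(np.ones((2, 4, 4)), np.zeros((2, 4, 4), dtype=bool))

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 2 ** 16))
    def test_integrated_equals_mean_times_count(self, seed):
        rng = np.random.default_rng(seed)
        vol = rng.uniform(0, 10, (3, 8, 8))
        mask = rng.random((3, 8, 8)) > 0.5
        if not mask.any():
            mask[0, 0, 0] = True
        res = mo.measure_cup(vol, mask)
        assert res.integrated_intensity == pytest.approx(
            res.mean_intensity * res.n_voxels, rel=1e-12)


class TestScorePhagocytosis:
    @staticmethod
    def _row(**kw):
        base = dict(experiment=0, fov=0, genotype="WT", time_min=15,
                    n_cells=10, n_internalized=3, n_associated=9, n_cups=0)
        base.update(kw)
        return base

    def test_enumerated_toy_table(self):
        table = pd.DataFrame([self._row()])
        out = mo.score_phagocytosis(table)
        assert out["pct_mean"].iloc[0] == pytest.approx(30.0)

    def test_identical_fovs_zero_sem(self):
        table = pd.DataFrame([self._row(experiment=e, fov=f)
                              for e in range(3) for f in range(4)])
        out = mo.score_phagocytosis(table)
        assert out["pct_sem"].iloc[0] == 0.0
        assert out["n_experiments"].iloc[0] == 3

    def test_binomial_table_mean_near_programmed_probability(self):
        table, _ = sg.gen_phagocytosis_table(sg.SynthConfig(seed=6),
                                             p_internal=0.3, cells_per_fov=50,
                                             n_fov=20)
        out = mo.score_phagocytosis(table)
        assert out["pct_mean"].iloc[0] == pytest.approx(30.0, abs=3.0)

    def test_count_ordering_violation_rejected(self):
        table = pd.DataFrame([self._row(n_internalized=5, n_associated=4)])
        with pytest.raises(ValueError, match="<="):
            mo.score_phagocytosis(table)

    def test_zero_cell_fov_dropped_with_warning(self):
        table = pd.DataFrame([self._row(), self._row(fov=1, n_cells=0,
                                                     n_internalized=0,
                                                     n_associated=0)])
        with pytest.warns(UserWarning, match="zero cells"):
            out = mo.score_phagocytosis(table)
        assert out["pct_mean"].iloc[0] == pytest.approx(30.0)

    def test_percentages_bounded_and_ordered(self):
        table, _ = sg.gen_phagocytosis_table(sg.SynthConfig(seed=8),
                                             p_internal=0.4, p_bound=0.8)
        internal = mo.score_phagocytosis(table, value="n_internalized")
        assoc = mo.score_phagocytosis(table, value="n_associated")
        assert 0 <= internal["pct_mean"].iloc[0] <= 100
        assert internal["pct_mean"].iloc[0] <= assoc["pct_mean"].iloc[0]


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        g = mo.compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert g.p_value == 1.0
        assert g.statistic == 0.0
        assert not g.significant

    def test_welch_used_when_sds_differ_markedly(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 5, 30)
        g = mo.compare_groups(a, b)
        assert "Welch" in g.test
        g2 = mo.compare_groups(a, rng.normal(0, 1.2, 30))
        assert g2.test == "unpaired t-test"

    def test_power_at_two_sigma_shift(self):
        """A 2-SD mean shift with n=20/group is detected essentially always."""
        rng = np.random.default_rng(1)
        hits = sum(mo.compare_groups(rng.normal(0, 1, 20),
                                     rng.normal(2, 1, 20)).significant
                   for _ in range(300))
        assert hits / 300 > 0.99

    def test_three_groups_run_anova_with_tukey(self):
        rng = np.random.default_rng(2)
        g = mo.compare_groups(rng.normal(0, 1, 15), rng.normal(0, 1, 15),
                              rng.normal(3, 1, 15))
        assert "ANOVA" in g.test
        assert g.significant
        assert g.posthoc is not None and len(g.posthoc) == 3

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            mo.compare_groups([1.0], [1.0, 2.0])
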
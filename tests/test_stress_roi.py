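"""Radial/tangential decomposition around region centroids."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import rotate_vector_field
from trophomech.fields import TractionField
from trophomech.stress_roi import (
    RegionOfInterest,
    StressDecomposition,
    StressTimeSeries,
    aggregate_window,
    check_area_match,
    compare_regions,
    decompose_field,
    decompose_vectors,
    dilate_roi,
)


def unit_lattice_traction(n, tx, ty, time=None):
    xs = np.arange(n, dtype=float)
    return TractionField(xs, xs, tx, ty, pixel_size=1.0, time=time)


def disk_roi(n, center, radius, label="syncytial"):
    return RegionOfInterest.from_disk((n, n), center, radius, label)


class TestROI:
    def test_centroid_is_areal_centroid(self):
        roi = disk_roi(64, (20.0, 30.0), 10)
        assert roi.centroid == pytest.approx((20.0, 30.0), abs=0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            RegionOfInterest(np.zeros((8, 8), bool), "syncytial")

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            RegionOfInterest(np.ones((8, 8), bool), "stromal")

    def test_polygon_roundtrip_via_json(self, tmp_path):
        import json

        spec = {
            "shape": [64, 64],
            "vertices": [[10, 10], [40, 10], [40, 30], [10, 30]],
            "label": "mononucleated",
            "fused_fraction": 0.27,
            "roi_id": "m1",
        }
        p = tmp_path / "roi.json"
        p.write_text(json.dumps(spec))
        roi = RegionOfInterest.from_json(p)
        assert roi.label == "mononucleated"
        assert roi.area_px > 0
        assert roi.roi_id == "m1"


class TestDilation:
    def test_zero_dilation_is_identity(self):
        roi = disk_roi(256, (128.0, 128.0), 30)
        out = dilate_roi(roi, 0)
        assert np.array_equal(out.mask, roi.mask)

    def test_disk_grows_by_radius_keeping_centroid(self):
        roi = disk_roi(512, (256.0, 256.0), 50)
        out = dilate_roi(roi, 80)
        # mask should be the 130 px disk
        expected = disk_roi(512, (256.0, 256.0), 130)
        agree = (out.mask == expected.mask).mean()
        assert agree > 0.999
        assert out.centroid == roi.centroid

    def test_area_monotone(self):
        roi = disk_roi(256, (128.0, 128.0), 20)
        assert dilate_roi(roi, 15).area_px >= roi.area_px

    def test_clipping_at_border_warns(self):
        roi = disk_roi(128, (10.0, 10.0), 8)
        with pytest.warns(UserWarning, match="clipped"):
            dilate_roi(roi, 30)


class TestDecomposition:
    def test_radial_alignment_east_of_centroid(self):
        n = 11
        tx = np.zeros((n, n))
        ty = np.zeros((n, n))
        tx[5, 8] = 1.0  # due east of centroid at (5, 5)
        mask = np.zeros((n, n), bool)
        mask[5, 8] = True
        roi = RegionOfInterest(mask, "syncytial", centroid=(5.0, 5.0))
        dec = decompose_field(unit_lattice_traction(n, tx, ty), roi)
        assert dec.mean_radial == pytest.approx(1.0)
        assert dec.mean_abs_tangential == pytest.approx(0.0)

    def test_tangential_orthogonality(self):
        n = 11
        tx = np.zeros((n, n))
        ty = np.zeros((n, n))
        ty[5, 8] = 1.0
        mask = np.zeros((n, n), bool)
        mask[5, 8] = True
        roi = RegionOfInterest(mask, "syncytial", centroid=(5.0, 5.0))
        dec = decompose_field(unit_lattice_traction(n, tx, ty), roi)
        assert dec.mean_radial == pytest.approx(0.0)
        assert dec.mean_abs_tangential == pytest.approx(1.0)

    def test_inward_unit_field_on_annulus(self):
        n = 41
        xs = np.arange(n, dtype=float)
        gx, gy = np.meshgrid(xs, xs)
        c = (n - 1) / 2.0
        rx, ry = gx - c, gy - c
        r = np.hypot(rx, ry)
        with np.errstate(invalid="ignore"):
            tx = np.where(r > 0, -rx / r, 0.0)
            ty = np.where(r > 0, -ry / r, 0.0)
        mask = (r >= 8) & (r <= 14)
        roi = RegionOfInterest(mask, "syncytial", centroid=(c, c))
        dec = decompose_field(unit_lattice_traction(n, tx, ty), roi)
        assert dec.mean_radial == pytest.approx(-1.0)
        assert dec.mean_abs_tangential == pytest.approx(0.0, abs=1e-12)

    @given(seed=st.integers(0, 500))
    def test_energy_conserved_per_vector(self, seed):
        n = 15
        rng = np.random.default_rng(seed)
        tx = rng.normal(size=(n, n))
        ty = rng.normal(size=(n, n))
        T = unit_lattice_traction(n, tx, ty)
        roi = disk_roi(n, ((n - 1) / 2, (n - 1) / 2), n // 3)
        s_r, s_t = decompose_vectors(T, roi)
        gx, gy = np.meshgrid(T.xs, T.ys)
        c = roi.centroid
        inside = roi.mask[gy.astype(int), gx.astype(int)] & (
            np.hypot(gx - c[0], gy - c[1]) > 1e-9
        )
        mag2 = tx[inside] ** 2 + ty[inside] ** 2
        np.testing.assert_allclose(s_r**2 + s_t**2, mag2, rtol=1e-12)

    def test_rotation_invariance(self):
        n = 33
        rng = np.random.default_rng(3)
        tx = rng.normal(size=(n, n))
        ty = rng.normal(size=(n, n))
        mask = np.zeros((n, n), bool)
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2
        mask[(xx - c - 3) ** 2 + (yy - c + 2) ** 2 <= 8**2] = True
        dec1 = decompose_field(
            unit_lattice_traction(n, tx, ty), RegionOfInterest(mask, "syncytial")
        )
        rtx, rty = rotate_vector_field(tx, ty)
        dec2 = decompose_field(
            unit_lattice_traction(n, rtx, rty),
            RegionOfInterest(np.rot90(mask, -1), "syncytial"),
        )
        assert dec2.mean_radial == pytest.approx(dec1.mean_radial, rel=1e-12)
        assert dec2.mean_abs_tangential == pytest.approx(
            dec1.mean_abs_tangential, rel=1e-12
        )

    def test_sign_flips_with_field_negation(self):
        n = 15
        rng = np.random.default_rng(4)
        tx = rng.normal(size=(n, n))
        ty = rng.normal(size=(n, n))
        roi = disk_roi(n, (7.0, 7.0), 5)
        d1 = decompose_field(unit_lattice_traction(n, tx, ty), roi)
        d2 = decompose_field(unit_lattice_traction(n, -tx, -ty), roi)
        assert d2.mean_radial == pytest.approx(-d1.mean_radial)
        assert d2.mean_abs_tangential == pytest.approx(d1.mean_abs_tangential)
        assert d1.mean_abs_tangential >= 0

    def test_roi_without_lattice_points_rejected(self):
        n = 15
        T = TractionField(
            np.arange(n) * 48.0, np.arange(n) * 48.0,
            np.zeros((n, n)), np.zeros((n, n)), 1.0,
        )
        mask = np.zeros((800, 800), bool)
        mask[700:710, 700:710] = True  # between/outside lattice points
        mask[705, 705] = True
        roi = RegionOfInterest(mask, "syncytial")
        with pytest.raises(ValueError, match="lattice"):
            decompose_field(T, roi)


def _series(values, times=None, label="syncytial"):
    times = times if times is not None else np.arange(len(values), dtype=float)
    roi = disk_roi(32, (16.0, 16.0), 8, label)
    decs = [
        StressDecomposition(time=float(t), mean_radial=float(v),
                            mean_abs_tangential=abs(float(v)), n_points=10)
        for t, v in zip(times, values)
    ]
    return StressTimeSeries(roi=roi, decompositions=decs)


class TestAggregation:
    def test_constant_series(self):
        s = _series([3.5] * 97, times=np.arange(97) * 0.5)
        sr, st_ = aggregate_window(s, 12, 48)
        assert sr == pytest.approx(3.5)

    def test_mean_of_time_index_window(self):
        times = np.arange(0, 48.5, 0.5)
        s = _series(times, times=times)
        sr, _ = aggregate_window(s, 12, 48)
        assert sr == pytest.approx(30.0)

    def test_window_choice_matters_with_onset_transient(self):
        times = np.arange(0, 48.5, 0.5)
        values = np.where(times < 8, 0.0, -2.0)  # transient before 12 h
        s = _series(values, times=times)
        full = aggregate_window(s, 0, 48)[0]
        late = aggregate_window(s, 12, 48)[0]
        assert late < full
        assert late == pytest.approx(-2.0)

    def test_empty_window_rejected(self):
        s = _series([1.0, 2.0], times=[0.0, 1.0])
        with pytest.raises(ValueError, match="window"):
            aggregate_window(s, 12, 48)


class TestComparison:
    def test_identical_constant_groups(self):
        out = compare_regions([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert out.t_statistic == 0.0 and out.p_value == 1.0

    def test_complete_separation_significant(self):
        out = compare_regions([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert out.p_value < 0.05

    def test_matches_group_statistics(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 3.0, 4.0, 5.0]
        out = compare_regions(a, b)
        assert out.mean_syncytial == pytest.approx(2.5)
        assert out.mean_mononucleated == pytest.approx(3.5)
        assert out.n_syncytial == 4

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_regions([1.0], [1.0, 2.0])

    def test_area_match_guard(self):
        a = disk_roi(256, (128.0, 128.0), 50)
        b = disk_roi(256, (128.0, 128.0), 50, label="mononucleated")
        check_area_match(a, b)  # identical areas pass
        c = disk_roi(256, (128.0, 128.0), 40, label="mononucleated")
        with pytest.raises(ValueError, match="area"):
            check_area_match(a, c)
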
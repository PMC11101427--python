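"""Boussinesq forward/inverse traction reconstruction."""

import warnings

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from conftest import rotate_vector_field
from trophomech.fields import DisplacementField, TractionField
from trophomech.fttc import (
    ElasticSubstrate,
    FTTCConfig,
    default_regularization,
    forward_displacement,
    invert_traction,
    traction_timeseries,
)


def annulus_traction(n=96, spacing_px=48.0, pixel_size=0.3086, peak=50.0, time=None):
    """Contractile ring: inward tractions on an annulus, zero net force."""
    xs = np.arange(n) * spacing_px
    gx, gy = np.meshgrid(xs * pixel_size, xs * pixel_size)
    cx = cy = xs.mean() * pixel_size
    X, Y = gx - cx, gy - cy
    r = np.hypot(X, Y)
    # ring small relative to the field so its displacement footprint decays
    # well inside the domain (the inversion truncates displacements at the
    # field edge)
    R = 0.056 * n * spacing_px * pixel_size
    mag = peak * np.exp(-((r - R) ** 2) / (2 * (R / 4) ** 2))
    with np.errstate(invalid="ignore"):
        tx = np.where(r > 1e-9, -mag * X / r, 0.0)
        ty = np.where(r > 1e-9, -mag * Y / r, 0.0)
    tx -= tx.mean()
    ty -= ty.mean()
    return TractionField(xs, xs, tx, ty, pixel_size, time=time)


@pytest.fixture(scope="module")
def smooth_traction():
    return annulus_traction()


class TestSubstrate:
    @pytest.mark.parametrize(
        "kw", [{"youngs_modulus": 0}, {"poisson_ratio": 0.5}, {"poisson_ratio": -0.1}]
    )
    def test_invalid_constants_rejected(self, kw):
        with pytest.raises(ValueError):
            ElasticSubstrate(**kw)


class TestForward:
    def test_zero_traction_zero_displacement(self, smooth_traction, substrate):
        zero = TractionField(
            smooth_traction.xs, smooth_traction.ys,
            np.zeros_like(smooth_traction.tx), np.zeros_like(smooth_traction.ty),
            smooth_traction.pixel_size,
        )
        d = forward_displacement(zero, substrate)
        assert np.allclose(d.u, 0) and np.allclose(d.v, 0)

    def test_doubling_modulus_halves_displacement(self, smooth_traction, substrate):
        d1 = forward_displacement(smooth_traction, substrate)
        stiff = ElasticSubstrate(
            youngs_modulus=2 * substrate.youngs_modulus,
            poisson_ratio=substrate.poisson_ratio,
            pixel_size=substrate.pixel_size,
        )
        d2 = forward_displacement(smooth_traction, stiff)
        assert np.allclose(d2.u, d1.u / 2, atol=1e-12)

    def test_dipole_displacement_antisymmetric(self, substrate):
        n = 64
        xs = np.arange(n) * 48.0
        tx = np.zeros((n, n))
        ty = np.zeros((n, n))
        # opposing point tractions mirrored about the vertical midline
        tx[n // 2, n // 2 - 8] = 100.0
        tx[n // 2, n // 2 + 7] = -100.0  # mirror of column n//2-8 about (n-1)/2
        T = TractionField(xs, xs, tx, ty, substrate.pixel_size)
        d = forward_displacement(T, substrate)
        assert np.allclose(d.u, -d.u[:, ::-1], atol=1e-9)

    def test_rotation_covariance(self, substrate):
        n = 33
        xs = np.arange(n, dtype=float)
        rng = np.random.default_rng(0)
        tx = gaussian_filter(rng.normal(size=(n, n)), 3)
        ty = gaussian_filter(rng.normal(size=(n, n)), 3)
        tx -= tx.mean()
        ty -= ty.mean()
        d1 = forward_displacement(TractionField(xs, xs, tx, ty, 1.0), substrate)
        rtx, rty = rotate_vector_field(tx, ty)
        d2 = forward_displacement(TractionField(xs, xs, rtx, rty, 1.0), substrate)
        ru, rv = rotate_vector_field(d1.u, d1.v)
        scale = np.abs(d1.u).max()
        assert np.allclose(d2.u, ru, atol=1e-4 * scale)
        assert np.allclose(d2.v, rv, atol=1e-4 * scale)


class TestInverse:
    def test_zero_displacement_zero_traction(self, smooth_traction, substrate):
        d = DisplacementField(
            smooth_traction.xs, smooth_traction.ys,
            np.zeros_like(smooth_traction.tx), np.zeros_like(smooth_traction.tx),
            np.ones_like(smooth_traction.tx),
            np.ones(smooth_traction.tx.shape, bool),
            smooth_traction.pixel_size,
        )
        T = invert_traction(d, substrate)
        assert np.allclose(T.tx, 0) and np.allclose(T.ty, 0)

    def test_roundtrip_small_regularization(self, smooth_traction, substrate):
        lam = 1e-6 * default_regularization(substrate, smooth_traction.spacing_um)
        cfg = FTTCConfig(regularization=lam)
        d = forward_displacement(smooth_traction, substrate, cfg)
        T = invert_traction(d, substrate, cfg)
        num = ((T.tx - smooth_traction.tx) ** 2 + (T.ty - smooth_traction.ty) ** 2).sum()
        den = (smooth_traction.tx**2 + smooth_traction.ty**2).sum()
        assert np.sqrt(num / den) < 0.05

    def test_linearity(self, smooth_traction, substrate):
        cfg = FTTCConfig(regularization=default_regularization(substrate, 14.8))
        d1 = forward_displacement(smooth_traction, substrate)
        d2 = DisplacementField(
            d1.xs, d1.ys, np.roll(d1.u, 3, axis=0), np.roll(d1.v, 3, axis=0),
            d1.corr, d1.valid, d1.pixel_size,
        )
        a, b = 2.5, -1.25
        combo = DisplacementField(
            d1.xs, d1.ys, a * d1.u + b * d2.u, a * d1.v + b * d2.v,
            d1.corr, d1.valid, d1.pixel_size,
        )
        T1 = invert_traction(d1, substrate, cfg)
        T2 = invert_traction(d2, substrate, cfg)
        Tc = invert_traction(combo, substrate, cfg)
        assert np.allclose(Tc.tx, a * T1.tx + b * T2.tx, atol=1e-8)
        assert np.allclose(Tc.ty, a * T1.ty + b * T2.ty, atol=1e-8)

    def test_rotation_covariance(self, substrate):
        n = 33
        xs = np.arange(n, dtype=float)
        rng = np.random.default_rng(1)
        u = gaussian_filter(rng.normal(size=(n, n)), 3)
        v = gaussian_filter(rng.normal(size=(n, n)), 3)
        ones = np.ones((n, n))
        d1 = DisplacementField(xs, xs, u, v, ones, ones.astype(bool), 1.0)
        ru, rv = rotate_vector_field(u, v)
        d2 = DisplacementField(xs, xs, ru, rv, ones, ones.astype(bool), 1.0)
        T1 = invert_traction(d1, substrate)
        T2 = invert_traction(d2, substrate)
        rtx, rty = rotate_vector_field(T1.tx, T1.ty)
        scale = np.abs(T1.tx).max()
        assert np.allclose(T2.tx, rtx, atol=1e-4 * scale)
        assert np.allclose(T2.ty, rty, atol=1e-4 * scale)

    def test_net_force_vanishes(self, smooth_traction, substrate):
        d = forward_displacement(smooth_traction, substrate)
        T = invert_traction(d, substrate)
        fx, fy = T.net_force()
        scale = (T.magnitude().max() * T.spacing_um**2) * T.tx.size
        assert abs(fx) < 1e-9 * scale and abs(fy) < 1e-9 * scale

    def test_noise_traction_vanishes_as_lambda_grows(self, substrate):
        n = 32
        xs = np.arange(n) * 48.0
        rng = np.random.default_rng(2)
        ones = np.ones((n, n))
        d = DisplacementField(
            xs, xs, rng.normal(size=(n, n)), rng.normal(size=(n, n)),
            ones, ones.astype(bool), substrate.pixel_size,
        )
        lam0 = default_regularization(substrate, d.spacing_um)
        mags = []
        for lam in [lam0, 10 * lam0, 100 * lam0, 1000 * lam0]:
            T = invert_traction(d, substrate, FTTCConfig(regularization=lam))
            mags.append(T.magnitude().mean())
        assert all(a > b for a, b in zip(mags[:-1], mags[1:]))

    def test_zero_regularization_warns(self, substrate, smooth_traction):
        d = forward_displacement(smooth_traction, substrate)
        with pytest.warns(UserWarning, match="regularization"):
            invert_traction(d, substrate, FTTCConfig(regularization=0.0))


class TestTimeseries:
    def test_count_and_order_preserved(self, substrate):
        fields = []
        for t in [0.0, 0.5, 1.0, 1.5]:
            f = forward_displacement(annulus_traction(n=24, time=t), substrate)
            f.time = t
            fields.append(f)
        out = traction_timeseries(fields[::-1], substrate)
        assert len(out) == 4
        assert [T.time for T in out] == [0.0, 0.5, 1.0, 1.5]

    def test_all_zero_series(self, substrate):
        n = 16
        xs = np.arange(n) * 48.0
        ones = np.ones((n, n))
        fields = [
            DisplacementField(xs, xs, np.zeros((n, n)), np.zeros((n, n)),
                              ones, ones.astype(bool), 0.3086, time=float(t))
            for t in range(3)
        ]
        out = traction_timeseries(fields, substrate)
        assert all(np.allclose(T.tx, 0) and np.allclose(T.ty, 0) for T in out)

    def test_mismatched_lattice_rejected(self, substrate):
        a = annulus_traction(n=16)
        b = annulus_traction(n=24)
        fa = forward_displacement(a, substrate)
        fb = forward_displacement(b, substrate)
        with pytest.raises(ValueError, match="lattice"):
            traction_timeseries([fa, fb], substrate)
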
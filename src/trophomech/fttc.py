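"""Fourier-transform traction cytometry on a linear-elastic half-space.

The substrate is modelled as a semi-infinite, homogeneous, isotropic
linear-elastic body whose free surface carries the cells.  In Fourier space
the surface displacement u~(k) produced by a surface traction T~(k) is
u~ = G~(k) T~(k) with the 2x2 Boussinesq tensor

    G~(k) = 2(1+nu) / (E k^3) * [ (1-nu)k^2 + nu ky^2,   -nu kx ky
                                  -nu kx ky,             (1-nu)k^2 + nu kx^2 ]

The inverse problem (displacement -> traction) is ill-posed at high
wavenumber, so it is solved per wavevector with 0th-order Tikhonov
regularization:  T~ = (G~^T G~ + lam I)^(-1) G~^T u~.  The k = 0 (DC) mode is
indeterminate for a half-space and is set to zero, which also enforces a
zero net force.  Fields are zero-padded before the FFT to suppress periodic
wrap-around from the finite field of view.

Units: E in Pa, lattice spacing and displacements in micrometres, wavevectors
in rad/um, tractions in Pa.  The regularization parameter lam carries the
units of G~^2 (um/Pa)^2; the default damps the inverse gain of the highest
resolvable wavevector roughly 100-fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .fields import DisplacementField, TractionField

__all__ = [
    "ElasticSubstrate",
    "FTTCConfig",
    "default_regularization",
    "forward_displacement",
    "invert_traction",
    "traction_timeseries",
]


@dataclass(frozen=True)
class ElasticSubstrate:
    """Elastic constants of the gel plus the imaging pixel size.

    Defaults are the polyacrylamide TFM substrate: E = 3900 Pa, nu = 0.457,
    0.3086 um pixels.
    """

    youngs_modulus: float = 3900.0
    poisson_ratio: float = 0.457
    pixel_size: float = 0.3086

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("poisson_ratio must lie in [0, 0.5)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass(frozen=True)
class FTTCConfig:
    """Inversion parameters: Tikhonov factor and zero-padding multiple.

    ``regularization=None`` selects the spectrum-scaled default at run time.
    """

    regularization: Optional[float] = None
    zero_pad_factor: int = 2

    def __post_init__(self) -> None:
        if self.regularization is not None and self.regularization < 0:
            raise ValueError("regularization must be >= 0")
        if int(self.zero_pad_factor) < 1:
            raise ValueError("zero_pad_factor must be >= 1")


def _wavevectors(ny: int, nx: int, spacing_um: float) -> tuple[np.ndarray, np.ndarray]:
    kx = 2 * np.pi * np.fft.fftfreq(nx, d=spacing_um)
    ky = 2 * np.pi * np.fft.fftfreq(ny, d=spacing_um)
    return np.meshgrid(kx, ky)


def _greens_tensor(
    kx: np.ndarray, ky: np.ndarray, substrate: ElasticSubstrate
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Components (Gxx, Gxy, Gyy) of the Boussinesq surface tensor; the
    singular k=0 entry is returned as 0 and handled by the DC convention."""
    E, nu = substrate.youngs_modulus, substrate.poisson_ratio
    k2 = kx**2 + ky**2
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + nu) / (E * k2**1.5)
        gxx = pref * ((1.0 - nu) * k2 + nu * ky**2)
        gyy = pref * ((1.0 - nu) * k2 + nu * kx**2)
        gxy = -pref * nu * kx * ky
    zero = k2 == 0
    for g in (gxx, gxy, gyy):
        g[zero] = 0.0
    return gxx, gxy, gyy


def default_regularization(
    substrate: ElasticSubstrate, spacing_um: float, damping: float = 100.0
) -> float:
    """Tikhonov factor that damps the inverse gain of the smallest kernel
    eigenvalue (reached at the Nyquist wavevector) about ``damping``-fold."""
    k_max = np.sqrt(2.0) * np.pi / spacing_um
    g_min = (
        2.0
        * (1.0 + substrate.poisson_ratio)
        * (1.0 - substrate.poisson_ratio)
        / (substrate.youngs_modulus * k_max)
    )
    return float(damping * g_min**2)


def _padded(arr: np.ndarray, factor: int) -> tuple[np.ndarray, tuple[slice, slice]]:
    ny, nx = arr.shape
    out = np.zeros((factor * ny, factor * nx))
    out[:ny, :nx] = arr
    return out, (slice(0, ny), slice(0, nx))


def forward_displacement(
    traction: TractionField,
    substrate: ElasticSubstrate,
    cfg: FTTCConfig | None = None,
) -> DisplacementField:
    """Surface displacement produced by a traction field (forward Boussinesq
    solve).  The DC traction mode is zeroed, so the input should be (close
    to) force balanced."""
    cfg = cfg or FTTCConfig()
    pad = int(cfg.zero_pad_factor)
    d = traction.spacing_um
    tx, crop = _padded(traction.tx, pad)
    ty, _ = _padded(traction.ty, pad)
    kx, ky = _wavevectors(*tx.shape, d)
    gxx, gxy, gyy = _greens_tensor(kx, ky, substrate)
    Tx = np.fft.fft2(tx)
    Ty = np.fft.fft2(ty)
    Tx[0, 0] = 0.0
    Ty[0, 0] = 0.0
    Ux = gxx * Tx + gxy * Ty
    Uy = gxy * Tx + gyy * Ty
    u = np.fft.ifft2(Ux).real[crop]
    v = np.fft.ifft2(Uy).real[crop]
    return DisplacementField(
        xs=traction.xs,
        ys=traction.ys,
        u=u,
        v=v,
        corr=np.ones_like(u),
        valid=np.ones(u.shape, dtype=bool),
        pixel_size=traction.pixel_size,
        time=traction.time,
    )


def invert_traction(
    displacement: DisplacementField,
    substrate: ElasticSubstrate,
    cfg: FTTCConfig | None = None,
) -> TractionField:
    """Recover the traction field from a displacement field (regularized
    inverse Boussinesq solve).

    Invalid vectors must already have been filled (see
    :func:`trophomech.piv.validate_and_fill`); the inversion uses every
    lattice value as-is.
    """
    cfg = cfg or FTTCConfig()
    if not displacement.valid.all():
        warnings.warn(
            "displacement field contains invalid vectors; their stored values "
            "are used as-is — run validate_and_fill first"
        )
    pad = int(cfg.zero_pad_factor)
    d = displacement.spacing_um
    lam = cfg.regularization
    if lam is None:
        lam = default_regularization(substrate, d)
    u, crop = _padded(displacement.u, pad)
    v, _ = _padded(displacement.v, pad)
    kx, ky = _wavevectors(*u.shape, d)
    gxx, gxy, gyy = _greens_tensor(kx, ky, substrate)
    if lam == 0.0:
        warnings.warn(
            "regularization is 0: high-wavevector noise is amplified unchecked"
        )
    U = np.fft.fft2(u)
    V = np.fft.fft2(v)
    # normal equations per wavevector; G~ is symmetric
    m00 = gxx * gxx + gxy * gxy + lam
    m01 = gxy * (gxx + gyy)
    m11 = gxy * gxy + gyy * gyy + lam
    r0 = gxx * U + gxy * V
    r1 = gxy * U + gyy * V
    det = m00 * m11 - m01 * m01
    with np.errstate(divide="ignore", invalid="ignore"):
        Tx = (m11 * r0 - m01 * r1) / det
        Ty = (m00 * r1 - m01 * r0) / det
    Tx[0, 0] = 0.0
    Ty[0, 0] = 0.0
    Tx[~np.isfinite(Tx)] = 0.0
    Ty[~np.isfinite(Ty)] = 0.0
    tx = np.fft.ifft2(Tx).real[crop]
    ty = np.fft.ifft2(Ty).real[crop]
    # re-zero the net force over the cropped (physical) region
    tx = tx - tx.mean()
    ty = ty - ty.mean()
    return TractionField(
        xs=displacement.xs,
        ys=displacement.ys,
        tx=tx,
        ty=ty,
        pixel_size=displacement.pixel_size,
        time=displacement.time,
    )


def traction_timeseries(
    fields: Sequence[DisplacementField],
    substrate: ElasticSubstrate,
    cfg: FTTCConfig | None = None,
) -> list[TractionField]:
    """Invert a displacement time series field-by-field, ordered by time.

    Missing timepoints are the caller's bookkeeping; no interpolation is
    performed here.
    """
    if not fields:
        return []
    ref = fields[0]
    for f in fields[1:]:
        if f.xs.shape != ref.xs.shape or not (
            np.allclose(f.xs, ref.xs) and np.allclose(f.ys, ref.ys)
        ):
            raise ValueError("displacement fields do not share a lattice")
    ordered = sorted(fields, key=lambda f: np.inf if f.time is None else f.time)
    return [invert_traction(f, substrate, cfg) for f in ordered]
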
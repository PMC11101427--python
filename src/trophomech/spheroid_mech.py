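"""Osmotic-compression mechanics for spheroids and calibration gels.

Dextran added to the medium exerts an isotropic osmotic pressure p on
bodies it cannot penetrate.  For a homogeneous isotropic linear-elastic
body loaded by a uniform pressure on its free surfaces (with a frictionless
roller support underneath), the uniform stress state sigma = -p I satisfies
equilibrium and every boundary condition exactly, so each linear dimension
contracts by the same strain

    eps = p (1 - 2 nu) / E,          E = 2 G (1 + nu),

where G comes from shear rheometry of the calibration gel.  This closed
form is the exact solution of the axisymmetric boundary-value problem a
finite-element solve would discretize, so the pressure behind a measured
diameter change follows directly as p = eps E / (1 - 2 nu).  Strain is
diametral (not volumetric) and compression is reported positive, matching
how spheroid compaction is measured: effective diameters from projected
areas assuming sphericity, referenced to t = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .fusion_metrics import SpheroidIntensity

__all__ = [
    "GelCalibration",
    "SpheroidTrack",
    "OsmoticLoad",
    "modulus_from_shear",
    "effective_diameter",
    "strain_timeseries",
    "pressure_from_strain",
    "strain_from_pressure",
    "calibrate_osmotic_load",
    "recover_pressure",
]


def modulus_from_shear(G: float, nu: float) -> float:
    """Young's modulus from the measured shear modulus: E = 2 G (1 + nu)."""
    if G <= 0:
        raise ValueError("shear modulus must be positive")
    if not (0.0 <= nu < 0.5):
        raise ValueError("poisson ratio must lie in [0, 0.5)")
    return 2.0 * G * (1.0 + nu)


@dataclass(frozen=True)
class GelCalibration:
    """Elastic calibration of the polyacrylamide reference gel.

    Defaults: G = 5150 Pa from shear rheometry, nu = 0.457.  Optional pre-
    and post-compression diameters record the measurement the calibration
    came from.
    """

    shear_modulus: float = 5150.0
    poisson_ratio: float = 0.457
    pre_diameter: Optional[float] = None
    post_diameter: Optional[float] = None

    def __post_init__(self) -> None:
        modulus_from_shear(self.shear_modulus, self.poisson_ratio)  # validates

    @property
    def youngs_modulus(self) -> float:
        return modulus_from_shear(self.shear_modulus, self.poisson_ratio)


def effective_diameter(area: float | np.ndarray) -> float | np.ndarray:
    """Diameter of the circle with the given projected area: d = 2 sqrt(A/pi)."""
    area = np.asarray(area, dtype=float)
    if np.any(area < 0):
        raise ValueError("area must be >= 0")
    d = 2.0 * np.sqrt(area / np.pi)
    return float(d) if d.ndim == 0 else d


@dataclass
class SpheroidTrack:
    """Geometry (and optionally marker intensity) of one spheroid over time.

    Construct from projected areas or directly from effective diameters;
    times are hours from dextran addition, t = 0 is the reference state.
    """

    times: np.ndarray
    diameters: np.ndarray
    intensity: Optional[SpheroidIntensity] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.times.shape != self.diameters.shape or self.times.ndim != 1:
            raise ValueError("times and diameters must be matching 1-D arrays")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.diameters <= 0):
            raise ValueError("diameters must be positive")
        if self.times[0] != 0:
            raise ValueError("track must start at t = 0 (reference state)")

    @classmethod
    def from_areas(cls, times, areas, **kw) -> "SpheroidTrack":
        return cls(times=np.asarray(times, float),
                   diameters=effective_diameter(np.asarray(areas, float)), **kw)

    @property
    def areas(self) -> np.ndarray:
        """Projected areas consistent with the diameters (circular projection)."""
        return np.pi * (self.diameters / 2.0) ** 2

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "diameter_um": self.diameters,
                "area_um2": self.areas,
                "strain": strain_timeseries(self),
            }
        )


def strain_timeseries(track: SpheroidTrack) -> np.ndarray:
    """Compressive strain eps(t) = (d(0) - d(t)) / d(0); compression > 0."""
    d0 = track.diameters[0]
    return (d0 - track.diameters) / d0


def pressure_from_strain(eps: float, E: float, nu: float) -> float:
    """Pressure behind a diametral compressive strain: p = eps E / (1 - 2 nu)."""
    if not (0.0 <= eps < 1.0):
        raise ValueError("strain must lie in [0, 1)")
    if not (0.0 <= nu < 0.5):
        raise ValueError(
            "poisson ratio must lie in [0, 0.5); at nu = 0.5 the body is "
            "incompressible and pressure is indeterminate from strain"
        )
    return eps * E / (1.0 - 2.0 * nu)


def strain_from_pressure(p: float, E: float, nu: float) -> float:
    """Diametral strain under uniform pressure: eps = p (1 - 2 nu) / E."""
    if p < 0:
        raise ValueError("pressure must be >= 0")
    if not (0.0 <= nu < 0.5):
        raise ValueError("poisson ratio must lie in [0, 0.5)")
    return p * (1.0 - 2.0 * nu) / E


@dataclass(frozen=True)
class OsmoticLoad:
    """Dextran concentration with the pressure inferred for it."""

    concentration: float  # mg/mL
    pressure: float  # Pa

    def __post_init__(self) -> None:
        if self.concentration < 0 or self.pressure < 0:
            raise ValueError("concentration and pressure must be >= 0")


def calibrate_osmotic_load(
    pre_d: float, post_d: float, gel: GelCalibration, concentration: float
) -> OsmoticLoad:
    """Infer the osmotic pressure of a dextran dose from the measured pre-
    and post-compression diameters of a calibration gel disc.

    Apparent swelling (post > pre) cannot come from a compressive osmotic
    load; it is reported as zero pressure with a warning.
    """
    if pre_d <= 0 or post_d <= 0:
        raise ValueError("diameters must be positive")
    if post_d > pre_d:
        warnings.warn("gel swelled (post > pre); reporting zero pressure")
        return OsmoticLoad(concentration=concentration, pressure=0.0)
    eps = (pre_d - post_d) / pre_d
    p = pressure_from_strain(eps, gel.youngs_modulus, gel.poisson_ratio)
    return OsmoticLoad(concentration=concentration, pressure=p)


def recover_pressure(
    track: SpheroidTrack, E: float, nu: float, t_min: float = 0.0
) -> float:
    """Pressure estimate from a spheroid track: mean compressive strain over
    t > t_min (equilibrium points) mapped through the closed form."""
    eps = strain_timeseries(track)
    sel = track.times > t_min
    if not sel.any():
        raise ValueError("no timepoints after t_min")
    return pressure_from_strain(float(np.clip(eps[sel].mean(), 0.0, None)), E, nu)
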
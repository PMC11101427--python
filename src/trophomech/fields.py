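"""Gridded vector-field containers shared by the PIV and traction stages.

Both fields live on a regular lattice in the image frame: origin at the
top-left pixel, x increasing rightward, y increasing downward.  Lattice
coordinates are stored in pixels (the native frame of the bead images);
physical positions in micrometres are derived through ``pixel_size``.
Displacements are stored in micrometres, tractions in pascals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["DisplacementField", "TractionField"]


def _check_regular(coords: np.ndarray, name: str) -> float:
    """Return the uniform spacing of a 1-D coordinate vector or raise."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 1 or coords.size < 2:
        raise ValueError(f"{name} must be a 1-D vector with >= 2 entries")
    steps = np.diff(coords)
    if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
        raise ValueError(f"{name} lattice is not regular")
    if steps[0] <= 0:
        raise ValueError(f"{name} must be strictly increasing")
    return float(steps[0])


@dataclass
class DisplacementField:
    """Bead displacement vectors on a regular lattice.

    Attributes
    ----------
    xs, ys : 1-D arrays of lattice coordinates in pixels.
    u, v : (ny, nx) displacement components in micrometres.
    corr : per-vector correlation coefficient in [-1, 1].
    valid : per-vector validity flag.
    pixel_size : micrometres per pixel.
    time : acquisition time in hours (optional).
    quality_ok : False when more than half the vectors failed validation.
    """

    xs: np.ndarray
    ys: np.ndarray
    u: np.ndarray
    v: np.ndarray
    corr: np.ndarray
    valid: np.ndarray
    pixel_size: float
    time: Optional[float] = None
    quality_ok: bool = True
    n_replaced: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        for name in ("u", "v", "corr"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.valid = np.asarray(self.valid, dtype=bool)
        _check_regular(self.xs, "xs")
        _check_regular(self.ys, "ys")
        shape = (self.ys.size, self.xs.size)
        for name in ("u", "v", "corr", "valid"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
        if np.any(self.corr > 1 + 1e-9):
            raise ValueError("correlation coefficients exceed 1")
        if self.valid.any() and not np.all(
            np.isfinite(self.u[self.valid]) & np.isfinite(self.v[self.valid])
        ):
            raise ValueError("non-finite displacement on a valid vector")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def spacing_px(self) -> float:
        return float(self.xs[1] - self.xs[0])

    @property
    def spacing_um(self) -> float:
        return self.spacing_px * self.pixel_size

    @property
    def u_px(self) -> np.ndarray:
        return self.u / self.pixel_size

    @property
    def v_px(self) -> np.ndarray:
        return self.v / self.pixel_size

    def magnitude(self) -> np.ndarray:
        """Displacement magnitude in micrometres."""
        return np.hypot(self.u, self.v)

    def copy(self) -> "DisplacementField":
        return replace(
            self,
            u=self.u.copy(),
            v=self.v.copy(),
            corr=self.corr.copy(),
            valid=self.valid.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table with one row per lattice vector."""
        gx, gy = np.meshgrid(self.xs, self.ys)
        return pd.DataFrame(
            {
                "x_px": gx.ravel(),
                "y_px": gy.ravel(),
                "u_px": self.u_px.ravel(),
                "v_px": self.v_px.ravel(),
                "u_um": self.u.ravel(),
                "v_um": self.v.ravel(),
                "corr": self.corr.ravel(),
                "valid": self.valid.ravel(),
                "time_h": np.nan if self.time is None else self.time,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, pixel_size: float) -> "DisplacementField":
        xs = np.unique(df["x_px"].to_numpy())
        ys = np.unique(df["y_px"].to_numpy())
        shape = (ys.size, xs.size)
        order = np.lexsort((df["x_px"].to_numpy(), df["y_px"].to_numpy()))
        time = df["time_h"].iloc[0] if "time_h" in df else None
        if time is not None and np.isnan(time):
            time = None
        return cls(
            xs=xs,
            ys=ys,
            u=df["u_um"].to_numpy()[order].reshape(shape),
            v=df["v_um"].to_numpy()[order].reshape(shape),
            corr=df["corr"].to_numpy()[order].reshape(shape),
            valid=df["valid"].to_numpy()[order].astype(bool).reshape(shape),
            pixel_size=pixel_size,
            time=time,
        )


@dataclass
class TractionField:
    """Traction stress vectors (Pa) on the same lattice as their source
    displacement field.  Houses the stress vector S used downstream for the
    radial/tangential decomposition."""

    xs: np.ndarray
    ys: np.ndarray
    tx: np.ndarray
    ty: np.ndarray
    pixel_size: float
    time: Optional[float] = None

    def __post_init__(self) -> None:
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        self.tx = np.asarray(self.tx, dtype=float)
        self.ty = np.asarray(self.ty, dtype=float)
        _check_regular(self.xs, "xs")
        _check_regular(self.ys, "ys")
        shape = (self.ys.size, self.xs.size)
        if self.tx.shape != shape or self.ty.shape != shape:
            raise ValueError(f"tx, ty must have shape {shape}")
        if not (np.all(np.isfinite(self.tx)) and np.all(np.isfinite(self.ty))):
            raise ValueError("traction components must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def spacing_px(self) -> float:
        return float(self.xs[1] - self.xs[0])

    @property
    def spacing_um(self) -> float:
        return self.spacing_px * self.pixel_size

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.tx, self.ty)

    def net_force(self) -> tuple[float, float]:
        """Lattice sum of traction times cell area (units Pa * um^2)."""
        cell = self.spacing_um**2
        return float(self.tx.sum() * cell), float(self.ty.sum() * cell)

    def to_dataframe(self) -> pd.DataFrame:
        gx, gy = np.meshgrid(self.xs, self.ys)
        return pd.DataFrame(
            {
                "x_px": gx.ravel(),
                "y_px": gy.ravel(),
                "t_x_Pa": self.tx.ravel(),
                "t_y_Pa": self.ty.ravel(),
                "time_h": np.nan if self.time is None else self.time,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, pixel_size: float) -> "TractionField":
        xs = np.unique(df["x_px"].to_numpy())
        ys = np.unique(df["y_px"].to_numpy())
        shape = (ys.size, xs.size)
        order = np.lexsort((df["x_px"].to_numpy(), df["y_px"].to_numpy()))
        time = df["time_h"].iloc[0] if "time_h" in df else None
        if time is not None and np.isnan(time):
            time = None
        return cls(
            xs=xs,
            ys=ys,
            tx=df["t_x_Pa"].to_numpy()[order].reshape(shape),
            ty=df["t_y_Pa"].to_numpy()[order].reshape(shape),
            pixel_size=pixel_size,
            time=time,
        )
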
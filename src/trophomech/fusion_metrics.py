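"""Fusion-efficiency statistics for trophoblast cultures.

Monolayer fusion is scored from per-field tallies: the total nuclei T, the
nuclei inside E-cadherin-delimited syncytia F, the number of syncytia S,
and the nuclei inside Syndecan-1-positive regions FS.  Two efficiencies are
derived:

    E-cadherin:  100 * (F - S + 1) / T      (0 when no syncytium exists)
    Syndecan-1:  100 * FS / T

The "+1" makes a single fully fused sheet (F = T, S = 1) score exactly
100%; when S = 0 the formula is short-circuited to 0 so an unfused field is
not credited with 1/T.  Spheroid fusion is scored volumetrically from
optical sections as integrated marker intensity per unit spheroid volume.
Because fusion competence drifts with passage number, treated values are
normalized to the mean of their batch's static control (fold values).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "FusionCounts",
    "SpheroidIntensity",
    "derive_counts",
    "efficiency_ecadherin",
    "efficiency_syndecan",
    "nuclear_density",
    "spheroid_fusion_au",
    "normalize_to_control",
]


@dataclass(frozen=True)
class FusionCounts:
    """Per-field tallies: T total nuclei, F fused nuclei, S syncytia,
    FS Syndecan-1-positive nuclei.  A syncytium holds at least 2 nuclei."""

    T: int
    F: int = 0
    S: int = 0
    FS: int = 0

    def __post_init__(self) -> None:
        for name in ("T", "F", "S", "FS"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.F > self.T:
            raise ValueError("fused nuclei F cannot exceed total nuclei T")
        if self.FS > self.T:
            raise ValueError("Syndecan-1-positive nuclei FS cannot exceed T")
        if self.S > 0 and self.F < 2 * self.S:
            raise ValueError("each syncytium needs >= 2 nuclei (F >= 2 S)")


@dataclass(frozen=True)
class SpheroidIntensity:
    """Per-optical-section marker readout of one spheroid.

    ``intensities`` are integrated densities (AU) per slice, ``areas`` the
    spheroid cross-section per slice (um^2); ``slice_spacing`` defaults to
    the 10 um light-sheet sectioning interval.
    """

    intensities: tuple[float, ...]
    areas: tuple[float, ...]
    slice_spacing: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "intensities", tuple(float(i) for i in self.intensities))
        object.__setattr__(self, "areas", tuple(float(a) for a in self.areas))
        if len(self.intensities) < 1 or len(self.intensities) != len(self.areas):
            raise ValueError("need >= 1 slice with matching intensity and area")
        if self.slice_spacing <= 0:
            raise ValueError("slice_spacing must be positive")
        if any(a < 0 for a in self.areas) or any(i < 0 for i in self.intensities):
            raise ValueError("intensities and areas must be >= 0")

    @property
    def total_volume(self) -> float:
        return float(sum(self.areas)) * self.slice_spacing

    @property
    def total_intensity(self) -> float:
        return float(sum(self.intensities))


def _nucleus_centroids(nuclei_mask: np.ndarray) -> list[tuple[int, int]]:
    lbl = cc_label(nuclei_mask)
    return [
        (int(round(p.centroid[0])), int(round(p.centroid[1])))
        for p in regionprops(lbl)
    ]


def derive_counts(
    nuclei_mask: np.ndarray,
    syncytium_mask: np.ndarray,
    syndecan_mask: np.ndarray,
) -> FusionCounts:
    """Count T, F, S, FS from binary masks by connected components.

    A nucleus belongs to a syncytium (or a Syndecan-1-positive region) when
    its centroid pixel lies inside the corresponding component — robust to
    partial boundary overlap.  Syncytium components holding fewer than two
    nucleus centroids are not counted as syncytia.
    """
    nuclei_mask = np.asarray(nuclei_mask, dtype=bool)
    syncytium_mask = np.asarray(syncytium_mask, dtype=bool)
    syndecan_mask = np.asarray(syndecan_mask, dtype=bool)
    if nuclei_mask.shape != syncytium_mask.shape or nuclei_mask.shape != syndecan_mask.shape:
        raise ValueError("masks must share a shape")
    centroids = _nucleus_centroids(nuclei_mask)
    T = len(centroids)
    if T == 0:
        return FusionCounts(T=0, F=0, S=0, FS=0)
    syn_lbl = cc_label(syncytium_mask)
    per_comp: dict[int, int] = {}
    FS = 0
    for r, c in centroids:
        comp = syn_lbl[r, c]
        if comp > 0:
            per_comp[comp] = per_comp.get(comp, 0) + 1
        if syndecan_mask[r, c]:
            FS += 1
    real = {comp: n for comp, n in per_comp.items() if n >= 2}
    return FusionCounts(T=T, F=sum(real.values()), S=len(real), FS=FS)


def efficiency_ecadherin(c: FusionCounts) -> float:
    """E-cadherin fusion efficiency, percent: 100 (F - S + 1) / T.

    Returns 0 when no syncytium exists (the +1 presumes at least one)."""
    if c.T == 0:
        raise ValueError("T must be > 0")
    if c.S == 0:
        return 0.0
    return 100.0 * (c.F - c.S + 1) / c.T


def efficiency_syndecan(c: FusionCounts) -> float:
    """Syndecan-1 fusion efficiency, percent: 100 FS / T."""
    if c.T == 0:
        raise ValueError("T must be > 0")
    return 100.0 * c.FS / c.T


def nuclear_density(T: int, area_mm2: float = 0.34) -> float:
    """Nuclei per mm^2 over the standard 0.34 mm^2 counting field."""
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    if T < 0:
        raise ValueError("T must be >= 0")
    return T / area_mm2


def spheroid_fusion_au(s: SpheroidIntensity) -> float:
    """Volumetric fusion proxy, AU/um^3: total integrated marker density
    over total spheroid volume (slice areas x spacing)."""
    vol = s.total_volume
    if vol <= 0:
        raise ValueError("total spheroid volume must be positive")
    return s.total_intensity / vol


def normalize_to_control(
    values: Sequence[float], control_values: Sequence[float]
) -> np.ndarray:
    """Fold values relative to the mean of the batch's control group."""
    control = np.asarray(control_values, dtype=float)
    if control.size == 0 or control.mean() <= 0:
        raise ValueError("control mean must be positive")
    return np.asarray(values, dtype=float) / control.mean()
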
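"""Synthetic inputs with known ground truth for every pipeline stage.

Every generator is deterministic under its seed and returns the ground
truth alongside the artifact, so PIV, traction inversion, ROI statistics,
fusion counting and spheroid mechanics can each be validated end to end
without microscope data.  What is emulated:

* bead images — fluorescent fiducial beads in the gel surface rendered as
  isotropic Gaussian spots plus additive Gaussian camera noise.  Deformed
  frames are produced by moving bead *centers* through the ground-truth
  displacement field (forward warping), never by resampling pixels, so the
  ground truth is free of interpolation bias;
* contraction movies — a time-lapse in which a circular "fusing patch"
  develops inward biaxial traction along its rim: tractions ramp linearly
  for 2 h after onset then plateau, displacements follow from the forward
  Boussinesq solve on the pixel lattice;
* fusion label masks — nuclei, syncytium outlines and Syndecan-1-positive
  regions laid out on a collision-free grid with exact known tallies;
* spheroid compaction tracks — diameters stepping to the linear-elastic
  equilibrium under a known osmotic pressure, with additive measurement
  noise on every post-reference timepoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional, Sequence

import numpy as np

from .fields import DisplacementField, TractionField
from .fttc import ElasticSubstrate, FTTCConfig, forward_displacement
from .fusion_metrics import FusionCounts
from .piv import PIVConfig, _window_centers
from .spheroid_mech import GelCalibration, SpheroidTrack, strain_from_pressure

__all__ = [
    "BeadImageSpec",
    "ContractionScenario",
    "ContractionMovie",
    "make_bead_pair",
    "make_contraction_movie",
    "make_fusion_labels",
    "make_spheroid_track",
]

# displacement callable: (x_px, y_px) arrays -> (u_px, v_px)
DisplacementFn = Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]


@dataclass(frozen=True)
class BeadImageSpec:
    """Rendering parameters for synthetic bead images.

    bead_density is beads per um^2 (about 11 beads per final 48 px window at
    the default 0.05/um^2); bead_sigma is the Gaussian spot width in px
    (0.5 um beads are near-diffraction-limited at 0.3086 um pixels);
    noise_sd is the camera noise as a fraction of spot amplitude.
    """

    bead_density: float = 0.05
    bead_sigma: float = 1.2
    noise_sd: float = 0.02
    image_size: tuple[int, int] = (384, 384)
    pixel_size: float = 0.3086
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bead_density <= 0:
            raise ValueError("bead_density must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.bead_sigma <= 0 or self.pixel_size <= 0:
            raise ValueError("bead_sigma and pixel_size must be positive")

    @property
    def n_beads(self) -> int:
        h, w = self.image_size
        return max(1, int(round(self.bead_density * h * w * self.pixel_size**2)))


@dataclass(frozen=True)
class ContractionScenario:
    """A circular patch that develops inward rim traction after onset.

    patch_center/patch_radius in um, peak_traction in Pa (soft-gel TFM
    scale), onset_time in h.  rim_width (um) is the Gaussian width of the
    traction annulus at the patch rim (default radius/4); the ramp to peak
    lasts ``ramp_duration`` hours.
    """

    patch_center: tuple[float, float]
    patch_radius: float
    peak_traction: float = 80.0
    onset_time: float = 6.0
    field_extent: tuple[int, int] = (384, 384)
    seed: int = 0
    rim_width: Optional[float] = None
    ramp_duration: float = 2.0

    def __post_init__(self) -> None:
        if self.patch_radius <= 0:
            raise ValueError("patch_radius must be positive")
        if self.peak_traction < 0:
            raise ValueError("peak_traction must be >= 0")
        if self.ramp_duration <= 0:
            raise ValueError("ramp_duration must be positive")
        # annulus-inside-field is checked at movie build time (needs pixel size)

    @property
    def rim_width_or_default(self) -> float:
        return self.rim_width if self.rim_width is not None else self.patch_radius / 4.0

    def ramp(self, t: float) -> float:
        """Traction scale factor at time t (h): 0 before onset, linear ramp
        for ramp_duration, then 1."""
        if t < self.onset_time:
            return 0.0
        return min(1.0, (t - self.onset_time) / self.ramp_duration)

    def traction_pattern(
        self, x_um: np.ndarray, y_um: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Peak-scale traction components (Pa) at positions given in um:
        a Gaussian annulus at the patch rim pointing toward the center."""
        cx, cy = self.patch_center
        rx = x_um - cx
        ry = y_um - cy
        r = np.hypot(rx, ry)
        mag = self.peak_traction * np.exp(
            -((r - self.patch_radius) ** 2) / (2.0 * self.rim_width_or_default**2)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            tx = np.where(r > 1e-9, -mag * rx / r, 0.0)
            ty = np.where(r > 1e-9, -mag * ry / r, 0.0)
        return tx, ty


def _render_beads(
    positions: np.ndarray,
    shape: tuple[int, int],
    sigma: float,
    amplitude: float = 800.0,
    background: float = 100.0,
) -> np.ndarray:
    """Render subpixel bead centers as Gaussian spots (no noise)."""
    img = np.full(shape, background, dtype=float)
    half = int(math.ceil(4 * sigma))
    H, W = shape
    for x, y in positions:
        ix0 = max(int(math.floor(x)) - half, 0)
        ix1 = min(int(math.floor(x)) + half + 1, W)
        iy0 = max(int(math.floor(y)) - half, 0)
        iy1 = min(int(math.floor(y)) + half + 1, H)
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        gx = np.arange(ix0, ix1)
        gy = np.arange(iy0, iy1)
        stamp = amplitude * np.exp(
            -(
                (gx[None, :] - x) ** 2 + (gy[:, None] - y) ** 2
            )
            / (2.0 * sigma**2)
        )
        img[iy0:iy1, ix0:ix1] += stamp
    return img


def _bead_positions(spec: BeadImageSpec, rng: np.random.Generator) -> np.ndarray:
    """Bead centers sampled over the frame plus a margin: the gel extends
    beyond the field of view, so beads displace into (and out of) the frame
    instead of vanishing at its edge."""
    h, w = spec.image_size
    m = 20.0 + 4.0 * spec.bead_sigma
    area_scale = (w + 2 * m) * (h + 2 * m) / (w * h)
    n = max(1, int(round(spec.n_beads * area_scale)))
    return rng.uniform([-m, -m], [w + m, h + m], size=(n, 2))


def _piv_lattice(shape: tuple[int, int], cfg: PIVConfig) -> tuple[np.ndarray, np.ndarray]:
    H, W = shape
    spacing = cfg.final_spacing_px
    window = cfg.window_sizes[-1]
    return (
        _window_centers(W, window, spacing).astype(float),
        _window_centers(H, window, spacing).astype(float),
    )


def make_bead_pair(
    spec: BeadImageSpec,
    field: DisplacementFn,
    cfg: PIVConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, DisplacementField]:
    """Reference/deformed bead image pair for a known displacement field.

    ``field`` maps pixel positions to pixel displacements.  Displacement
    magnitudes above a quarter of the smallest interrogation window are
    refused: windowed cross-correlation could not resolve them and the
    fixture would be silently unusable.  The returned ground truth is the
    field sampled on the PIV output lattice (displacements in um).
    """
    cfg = cfg or PIVConfig(pixel_size=spec.pixel_size)
    rng = np.random.default_rng(spec.seed)
    pos = _bead_positions(spec, rng)
    u, v = field(pos[:, 0], pos[:, 1])
    limit = min(cfg.window_sizes) / 4.0
    max_mag = float(np.hypot(u, v).max()) if len(pos) else 0.0
    if max_mag >= limit:
        raise ValueError(
            f"displacement magnitude {max_mag:.2f} px exceeds a quarter of the "
            f"smallest PIV window ({limit:.1f} px); reduce the field amplitude"
        )
    reference = _render_beads(pos, spec.image_size, spec.bead_sigma)
    moved = pos + np.stack([u, v], axis=1)
    deformed = _render_beads(moved, spec.image_size, spec.bead_sigma)
    if spec.noise_sd > 0:
        reference = reference + rng.normal(0, spec.noise_sd * 800.0, spec.image_size)
        deformed = deformed + rng.normal(0, spec.noise_sd * 800.0, spec.image_size)
    xs, ys = _piv_lattice(spec.image_size, cfg)
    gx, gy = np.meshgrid(xs, ys)
    gu, gv = field(gx, gy)
    truth = DisplacementField(
        xs=xs,
        ys=ys,
        u=gu * spec.pixel_size,
        v=gv * spec.pixel_size,
        corr=np.ones_like(gu),
        valid=np.ones(gu.shape, dtype=bool),
        pixel_size=spec.pixel_size,
    )
    return reference, deformed, truth


@dataclass
class ContractionMovie:
    """A synthetic TFM acquisition plus its ground truth."""

    frames: np.ndarray  # (n_times, H, W)
    times: np.ndarray  # hours
    truth_tractions: list[TractionField]  # on the PIV lattice, per time
    truth_displacement_um: tuple[np.ndarray, np.ndarray]  # peak-scale, pixel lattice
    scenario: ContractionScenario
    spec: BeadImageSpec
    ramp: np.ndarray = dc_field(default=None)  # scale factor per frame


def make_contraction_movie(
    scenario: ContractionScenario,
    substrate: ElasticSubstrate,
    times: Sequence[float],
    spec: BeadImageSpec | None = None,
    cfg: PIVConfig | None = None,
) -> ContractionMovie:
    """Render a bead time-lapse of a contracting patch with known tractions.

    The peak-scale traction pattern is solved forward (Boussinesq, pixel
    lattice) once; displacements at every time are that solution scaled by
    the onset ramp, so tractions are exactly zero before onset and plateau
    at peak after the ramp.  Bead frames are rendered from the displaced
    bead centers; ground-truth tractions are the analytic pattern sampled
    on the PIV output lattice.
    """
    times = np.asarray(list(times), dtype=float)
    if times.size == 0 or times[0] != 0:
        raise ValueError("times must start at 0 (reference frame)")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    spec = spec or BeadImageSpec(
        image_size=scenario.field_extent,
        pixel_size=substrate.pixel_size,
        seed=scenario.seed,
    )
    if spec.image_size != scenario.field_extent:
        raise ValueError("bead image size must match the scenario field extent")
    px = spec.pixel_size
    H, W = spec.image_size
    cx, cy = scenario.patch_center
    reach = scenario.patch_radius + 3 * scenario.rim_width_or_default
    if (
        cx - reach < 0 or cy - reach < 0
        or cx + reach > W * px or cy + reach > H * px
    ):
        raise ValueError("contractile patch (rim annulus) extends outside the field")

    # forward solve at peak traction on the pixel lattice
    xs_px = np.arange(W, dtype=float)
    ys_px = np.arange(H, dtype=float)
    gx, gy = np.meshgrid(xs_px * px, ys_px * px)
    tx, ty = scenario.traction_pattern(gx, gy)
    peak_traction_field = TractionField(
        xs=xs_px, ys=ys_px, tx=tx, ty=ty, pixel_size=px
    )
    disp = forward_displacement(peak_traction_field, substrate, FTTCConfig())
    u_px = disp.u / px
    v_px = disp.v / px

    rng = np.random.default_rng(spec.seed)
    pos = _bead_positions(spec, rng)
    from scipy.interpolate import RegularGridInterpolator

    itp_u = RegularGridInterpolator(
        (ys_px, xs_px), u_px, method="linear", bounds_error=False, fill_value=0.0
    )
    itp_v = RegularGridInterpolator(
        (ys_px, xs_px), v_px, method="linear", bounds_error=False, fill_value=0.0
    )
    pts = np.stack([pos[:, 1], pos[:, 0]], axis=1)
    bead_u = itp_u(pts)
    bead_v = itp_v(pts)

    lat_xs, lat_ys = _piv_lattice(spec.image_size, cfg or PIVConfig(pixel_size=px))
    lgx, lgy = np.meshgrid(lat_xs * px, lat_ys * px)
    lat_tx, lat_ty = scenario.traction_pattern(lgx, lgy)

    frames = np.empty((times.size, H, W))
    truths: list[TractionField] = []
    scales = np.array([scenario.ramp(t) for t in times])
    for i, (t, s) in enumerate(zip(times, scales)):
        moved = pos + s * np.stack([bead_u, bead_v], axis=1)
        frame = _render_beads(moved, spec.image_size, spec.bead_sigma)
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0, spec.noise_sd * 800.0, spec.image_size)
        frames[i] = frame
        truths.append(
            TractionField(
                xs=lat_xs, ys=lat_ys, tx=s * lat_tx, ty=s * lat_ty,
                pixel_size=px, time=float(t),
            )
        )
    return ContractionMovie(
        frames=frames,
        times=times,
        truth_tractions=truths,
        truth_displacement_um=(disp.u, disp.v),
        scenario=scenario,
        spec=spec,
        ramp=scales,
    )


def make_fusion_labels(
    n_nuclei: int,
    n_syncytia: int,
    nuclei_per_syncytium: Sequence[int],
    fraction_syndecan: float = 1.0,
    seed: int = 0,
    image_size: tuple[int, int] = (512, 512),
) -> tuple[np.ndarray, np.ndarray, np.ndarray, FusionCounts]:
    """Label masks (nuclei, syncytium, Syndecan-1) with exact known tallies.

    Nuclei are 4 px-radius disks on a collision-free 14 px grid; each
    syncytium is a rectangle covering the grid cells of its nuclei, shrunk
    so neighbouring syncytia stay disconnected.  ``fraction_syndecan`` is
    the fraction of syncytia marked Syndecan-1-positive (selection is
    seed-deterministic); FS in the returned ground truth is the nucleus
    count of the selected syncytia.
    """
    nuclei_per_syncytium = [int(m) for m in nuclei_per_syncytium]
    if len(nuclei_per_syncytium) != n_syncytia:
        raise ValueError("nuclei_per_syncytium must list one count per syncytium")
    if any(m < 2 for m in nuclei_per_syncytium):
        raise ValueError("each syncytium needs >= 2 nuclei")
    n_fused = sum(nuclei_per_syncytium)
    if n_fused > n_nuclei:
        raise ValueError("sum of syncytial nuclei exceeds total nuclei")
    if not (0.0 <= fraction_syndecan <= 1.0):
        raise ValueError("fraction_syndecan must lie in [0, 1]")

    cell = 14  # px per grid cell
    margin = 2  # px shrink of syncytium rectangles
    radius = 4  # px nucleus disk radius
    H, W = image_size
    ncols_total = W // cell
    nrows_total = H // cell

    nuclei = np.zeros(image_size, dtype=bool)
    syncytium = np.zeros(image_size, dtype=bool)
    syndecan = np.zeros(image_size, dtype=bool)

    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk_stamp = xx**2 + yy**2 <= radius**2

    def put_nucleus(row: int, col: int) -> None:
        cy = row * cell + cell // 2
        cx = col * cell + cell // 2
        nuclei[cy - radius : cy + radius + 1, cx - radius : cx + radius + 1] |= disk_stamp

    # shelf-pack syncytium blocks (in grid cells, 1-cell separation), then singles
    cursor_row, cursor_col, shelf_h = 0, 0, 0
    rects: list[tuple[int, int, int, int]] = []  # (r0, c0, rows, cols) in cells

    def place_block(rows: int, cols: int) -> tuple[int, int]:
        nonlocal cursor_row, cursor_col, shelf_h
        if cursor_col + cols > ncols_total:
            cursor_row += shelf_h + 1
            cursor_col, shelf_h = 0, 0
        if cursor_row + rows > nrows_total or cols > ncols_total:
            raise ValueError(
                f"requested tallies do not fit in a {image_size} image"
            )
        r0, c0 = cursor_row, cursor_col
        cursor_col += cols + 1
        shelf_h = max(shelf_h, rows)
        return r0, c0

    for m in nuclei_per_syncytium:
        cols = int(math.ceil(math.sqrt(m)))
        rows = int(math.ceil(m / cols))
        r0, c0 = place_block(rows, cols)
        placed = 0
        for r in range(rows):
            for c in range(cols):
                if placed >= m:
                    break
                put_nucleus(r0 + r, c0 + c)
                placed += 1
        rects.append((r0, c0, rows, cols))
        y0, x0 = r0 * cell + margin, c0 * cell + margin
        y1, x1 = (r0 + rows) * cell - margin, (c0 + cols) * cell - margin
        syncytium[y0:y1, x0:x1] = True

    for _ in range(n_nuclei - n_fused):
        r0, c0 = place_block(1, 1)
        put_nucleus(r0, c0)

    rng = np.random.default_rng(seed)
    n_pos = int(round(fraction_syndecan * n_syncytia))
    chosen = rng.permutation(n_syncytia)[:n_pos] if n_syncytia else np.array([], int)
    FS = 0
    for idx in chosen:
        r0, c0, rows, cols = rects[idx]
        y0, x0 = r0 * cell + margin, c0 * cell + margin
        y1, x1 = (r0 + rows) * cell - margin, (c0 + cols) * cell - margin
        syndecan[y0:y1, x0:x1] = True
        FS += nuclei_per_syncytium[idx]

    truth = FusionCounts(T=n_nuclei, F=n_fused, S=n_syncytia, FS=FS)
    return nuclei, syncytium, syndecan, truth


def make_spheroid_track(
    d0: float,
    pressure: float,
    body: GelCalibration,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SpheroidTrack:
    """Spheroid diameter track under a constant osmotic pressure.

    The diameter steps to the linear-elastic equilibrium
    d0 (1 - eps) with eps = p (1 - 2 nu) / E for every t > 0; measurement
    noise (um) is added to post-reference timepoints only, keeping t = 0 the
    exact reference so the strain track starts at zero.
    """
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    if pressure < 0:
        raise ValueError("pressure must be >= 0")
    times = np.asarray(list(times), dtype=float)
    if times.size == 0 or times[0] != 0:
        raise ValueError("times must start at 0")
    eps = strain_from_pressure(pressure, body.youngs_modulus, body.poisson_ratio)
    diam = np.full(times.size, d0 * (1.0 - eps))
    diam[0] = d0
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        diam[1:] += rng.normal(0.0, noise_sd, times.size - 1)
    return SpheroidTrack(times=times, diameters=diam)
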
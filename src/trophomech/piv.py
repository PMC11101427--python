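"""Bead-displacement recovery by multi-pass windowed cross-correlation.

The estimator follows standard iterative PIV practice: a coarse pass with
large interrogation windows seeds finer passes through a predictor field
that offsets each window in the deformed image, so the residual shift each
pass has to resolve stays small.  Cross-correlation uses mean-subtracted
(normalized) windows computed via FFT, with a three-point Gaussian fit for
subpixel peak location.  The default window cascade is 128 -> 64 -> 48 px
with a correlation-coefficient acceptance threshold of 0.6; at a pixel size
of 0.3086 um the final non-overlapping 48 px lattice has ~14.8 um spacing.

The first frame of a time series (t = 0, induction) is always the reference,
so recovered displacements — and the tractions derived from them — are
relative to the pre-induction configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from skimage.registration import phase_cross_correlation

from .fields import DisplacementField

__all__ = ["PIVConfig", "align_to_reference", "iterative_piv", "validate_and_fill"]


@dataclass(frozen=True)
class PIVConfig:
    """Parameters of the multi-pass PIV estimator.

    window_sizes must be strictly decreasing; ``final_spacing_rule`` decides
    whether final-pass windows tile without overlap ("window") or overlap by
    half ("half-window").
    """

    window_sizes: tuple[int, ...] = (128, 64, 48)
    correlation_threshold: float = 0.6
    pixel_size: float = 0.3086
    final_spacing_rule: str = "window"

    def __post_init__(self) -> None:
        ws = tuple(int(w) for w in self.window_sizes)
        object.__setattr__(self, "window_sizes", ws)
        if len(ws) < 1 or any(w <= 2 for w in ws):
            raise ValueError("window_sizes must contain sizes > 2 px")
        if len(ws) > 1 and not all(a > b for a, b in zip(ws[:-1], ws[1:])):
            raise ValueError("window_sizes must be strictly decreasing")
        if not (0.0 < self.correlation_threshold < 1.0):
            raise ValueError("correlation_threshold must lie in (0, 1)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.final_spacing_rule not in ("window", "half-window"):
            raise ValueError("final_spacing_rule must be 'window' or 'half-window'")

    @property
    def final_spacing_px(self) -> int:
        w = self.window_sizes[-1]
        return w if self.final_spacing_rule == "window" else w // 2

    @property
    def final_spacing_um(self) -> float:
        return self.final_spacing_px * self.pixel_size


def align_to_reference(
    stack: np.ndarray, reference_index: int = 0, upsample_factor: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Register every frame of a stack to one reference frame.

    Whole-frame cross-correlation (subpixel, via Fourier upsampling) removes
    rigid stage drift before windowed PIV.  Returns the aligned stack and the
    per-frame (dy, dx) shifts that were applied.

    A featureless (flat) frame cannot be registered; it is passed through
    unshifted with a warning.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (n_frames, H, W) with >= 2 frames")
    reference = stack[reference_index]
    aligned = np.empty_like(stack)
    shifts = np.zeros((stack.shape[0], 2))
    for i, frame in enumerate(stack):
        if i == reference_index:
            aligned[i] = frame
            continue
        if np.ptp(frame) == 0 or np.ptp(reference) == 0:
            warnings.warn(f"frame {i} is featureless; assuming zero drift")
            aligned[i] = frame
            continue
        # plain (non-whitened) cross-correlation: more accurate than phase
        # normalization on sparse bead images
        shift, _, _ = phase_cross_correlation(
            reference, frame, upsample_factor=upsample_factor, normalization=None
        )
        shifts[i] = shift
        aligned[i] = ndimage.shift(frame, shift, order=1, mode="nearest")
    return aligned, shifts


def _window_centers(length: int, window: int, spacing: int) -> np.ndarray:
    """Centers of interrogation windows tiling one image axis, centred in
    the frame so leftover margin is split evenly."""
    n = (length - window) // spacing + 1
    if n < 1:
        raise ValueError(f"window {window} px does not fit in {length} px image")
    span = (n - 1) * spacing + window
    start = (length - span) // 2 + window // 2
    return start + spacing * np.arange(n)


def _gauss3(c_m: float, c_0: float, c_p: float) -> float:
    """Subpixel peak offset from three correlation samples at -1, 0, +1.

    Gaussian (log-space parabola) fit when all samples are positive,
    parabolic otherwise; result clamped to [-1, 1].
    """
    if c_m > 0 and c_0 > 0 and c_p > 0:
        lm, l0, lp = np.log(c_m), np.log(c_0), np.log(c_p)
        denom = lm - 2 * l0 + lp
        if denom < 0:
            return float(np.clip(0.5 * (lm - lp) / denom, -1, 1))
    denom = c_m - 2 * c_0 + c_p
    if denom >= 0:
        return 0.0
    return float(np.clip(0.5 * (c_m - c_p) / denom, -1, 1))


def _correlate_window(
    ref_win: np.ndarray, cur_win: np.ndarray, search_radius: int
) -> tuple[float, float, float, bool]:
    """Residual (dx, dy) of ``cur_win`` relative to ``ref_win`` plus the
    normalized correlation coefficient at the peak.

    The circular correlation plane is searched only within ``search_radius``
    of zero lag; an all-equal (degenerate) plane flags the vector invalid.
    """
    a = ref_win - ref_win.mean()
    b = cur_win - cur_win.mean()
    na = np.sqrt((a * a).sum())
    nb = np.sqrt((b * b).sum())
    if na == 0 or nb == 0:
        return 0.0, 0.0, 0.0, False
    # zero-padded linear correlation (no periodic wrap): plane[c+dy, c+dx]
    # = sum a(x) b(x+d), full lag range with center c = w-1
    w = ref_win.shape[0]
    n = 2 * w
    A = np.fft.fft2(a, s=(n, n))
    B = np.fft.fft2(b, s=(n, n))
    plane = np.fft.ifft2(np.conj(A) * B).real
    plane = np.roll(plane, (w - 1, w - 1), axis=(0, 1))[: 2 * w - 1, : 2 * w - 1]
    if np.ptp(plane) == 0:
        return 0.0, 0.0, 0.0, False
    c = w - 1
    lo, hi = c - search_radius, c + search_radius + 1
    sub = plane[lo:hi, lo:hi]
    iy, ix = np.unravel_index(np.argmax(sub), sub.shape)
    py, px = iy + lo, ix + lo
    peak = plane[py, px]
    corr = float(peak / (na * nb))
    # subpixel refinement needs interior neighbours
    if 0 < py < plane.shape[0] - 1:
        dy_sub = _gauss3(plane[py - 1, px], peak, plane[py + 1, px])
    else:
        dy_sub = 0.0
    if 0 < px < plane.shape[1] - 1:
        dx_sub = _gauss3(plane[py, px - 1], peak, plane[py, px + 1])
    else:
        dx_sub = 0.0
    return float(px - c + dx_sub), float(py - c + dy_sub), corr, True


def _piv_pass(
    reference: np.ndarray,
    current: np.ndarray,
    window: int,
    spacing: int,
    pred_u: np.ndarray,
    pred_v: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One correlation pass on the lattice (xs, ys) with a predictor field
    (px) used to offset the deformed-image window."""
    H, W = reference.shape
    h = window // 2
    u = np.zeros((ys.size, xs.size))
    v = np.zeros_like(u)
    corr = np.zeros_like(u)
    valid = np.zeros(u.shape, dtype=bool)
    search_radius = max(2, window // 4)
    for j, cy in enumerate(ys):
        for i, cx in enumerate(xs):
            r0, c0 = int(cy) - h, int(cx) - h
            ou = int(np.round(pred_u[j, i]))
            ov = int(np.round(pred_v[j, i]))
            # keep the full predictor offset near the border by sliding BOTH
            # windows inward together (locally the field is smooth, so the
            # vector still describes this grid point)
            r1 = min(max(r0 + ov, 0), H - window)
            c1 = min(max(c0 + ou, 0), W - window)
            r0e = min(max(r1 - ov, 0), H - window)
            c0e = min(max(c1 - ou, 0), W - window)
            ov, ou = r1 - r0e, c1 - c0e
            ref_win = reference[r0e : r0e + window, c0e : c0e + window]
            cur_win = current[r1 : r1 + window, c1 : c1 + window]
            dx, dy, cc, ok = _correlate_window(ref_win, cur_win, search_radius)
            if ok:
                u[j, i] = ou + dx
                v[j, i] = ov + dy
                corr[j, i] = cc
                valid[j, i] = True
            else:
                u[j, i] = pred_u[j, i]
                v[j, i] = pred_v[j, i]
    return u, v, corr, valid


def _interp_to(
    xs_from: np.ndarray, ys_from: np.ndarray, values: np.ndarray,
    xs_to: np.ndarray, ys_to: np.ndarray,
) -> np.ndarray:
    """Bilinear interpolation of a lattice field onto a new lattice,
    clamping query points to the source hull (nearest-edge extension)."""
    if xs_from.size == 1 or ys_from.size == 1:
        return np.full((ys_to.size, xs_to.size), float(values.mean()))
    itp = RegularGridInterpolator(
        (ys_from, xs_from), values, method="linear", bounds_error=False
    )
    gy = np.clip(ys_to, ys_from[0], ys_from[-1])
    gx = np.clip(xs_to, xs_from[0], xs_from[-1])
    GY, GX = np.meshgrid(gy, gx, indexing="ij")
    return itp(np.stack([GY.ravel(), GX.ravel()], axis=1)).reshape(ys_to.size, xs_to.size)


def iterative_piv(
    reference: np.ndarray, current: np.ndarray, cfg: PIVConfig | None = None
) -> DisplacementField:
    """Estimate the displacement field of ``current`` relative to ``reference``.

    Each pass halves (roughly) the interrogation window; the previous pass's
    field — median-smoothed 3x3 and bilinearly interpolated onto the new
    lattice — offsets the deformed-image windows, so the correlation only has
    to resolve the residual.  The subpixel peak comes from a three-point
    Gaussian fit.  Output displacements are converted to micrometres.
    """
    cfg = cfg or PIVConfig()
    reference = np.asarray(reference, dtype=float)
    current = np.asarray(current, dtype=float)
    if reference.shape != current.shape:
        raise ValueError("reference and current images must share a shape")
    H, W = reference.shape
    if cfg.window_sizes[0] > min(H, W) // 2:
        raise ValueError("largest window exceeds half the image size")

    xs_prev = ys_prev = None
    u_prev = v_prev = None
    n_passes = len(cfg.window_sizes)
    for k, window in enumerate(cfg.window_sizes):
        spacing = cfg.final_spacing_px if k == n_passes - 1 else window
        xs = _window_centers(W, window, spacing).astype(float)
        ys = _window_centers(H, window, spacing).astype(float)
        if u_prev is None:
            pred_u = np.zeros((ys.size, xs.size))
            pred_v = np.zeros_like(pred_u)
        else:
            su = ndimage.median_filter(u_prev, size=3, mode="nearest")
            sv = ndimage.median_filter(v_prev, size=3, mode="nearest")
            pred_u = _interp_to(xs_prev, ys_prev, su, xs, ys)
            pred_v = _interp_to(xs_prev, ys_prev, sv, xs, ys)
        u, v, corr, valid = _piv_pass(
            reference, current, window, spacing, pred_u, pred_v, xs, ys
        )
        xs_prev, ys_prev, u_prev, v_prev = xs, ys, u, v

    return DisplacementField(
        xs=xs,
        ys=ys,
        u=u * cfg.pixel_size,
        v=v * cfg.pixel_size,
        corr=corr,
        valid=valid,
        pixel_size=cfg.pixel_size,
    )


def validate_and_fill(field: DisplacementField, cfg: PIVConfig | None = None) -> DisplacementField:
    """Reject low-correlation vectors and fill them from their neighbours.

    Vectors with correlation below the acceptance threshold are flagged
    invalid and replaced by the median of their valid 8-neighbours, iterating
    until no invalid vector has a valid neighbour.  If more than half the
    field fails the threshold the result carries ``quality_ok=False``.
    """
    cfg = cfg or PIVConfig(pixel_size=field.pixel_size)
    out = field.copy()
    bad = (out.corr < cfg.correlation_threshold) | ~out.valid
    out.valid = ~bad
    frac_bad = bad.mean()
    if frac_bad > 0.5:
        out.quality_ok = False
        warnings.warn(
            f"{frac_bad:.0%} of vectors fell below the correlation threshold"
        )
    n_replaced = 0
    ny, nx = out.u.shape
    filled = ~bad
    while True:
        progress = False
        todo = np.argwhere(~filled)
        for j, i in todo:
            ys = slice(max(j - 1, 0), min(j + 2, ny))
            xs = slice(max(i - 1, 0), min(i + 2, nx))
            nb = filled[ys, xs].copy()
            nb[j - ys.start, i - xs.start] = False
            if nb.any():
                out.u[j, i] = np.median(out.u[ys, xs][nb])
                out.v[j, i] = np.median(out.v[ys, xs][nb])
                filled[j, i] = True
                n_replaced += 1
                progress = True
        if not progress:
            break
    out.n_replaced = n_replaced
    return out
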
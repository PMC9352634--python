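"""Raster-scan processing: trace statistics (SNR, dF/F0), projections, frame
registration, SNR-driven pixel selection, longitudinal segmentation alignment,
and autoregressive calcium deconvolution.

The SNR of a fluorescence trace is defined against its own low-fluorescence
tail: values strictly below the 25th percentile form the noise sample ``f25``
and

    SNR(f) = (max f - mean(f25)) / std(f25)

with the population standard deviation.  dF/F0 uses the analogous sub-median
sample ``f50`` as baseline: (f - mean(f50)) / mean(f50).  Percentiles are the
linearly interpolated empirical quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, signal
from scipy.linalg import solve_toeplitz
from skimage.measure import EllipseModel

from .errors import ConfigError, DataError, DegenerateTraceError
from .io import RasterMovie, ROI, Segmentation

__all__ = [
    "Trace",
    "RegistrationResult",
    "snr",
    "dff",
    "compute_projections",
    "register_raster",
    "snr_maximize_pixels",
    "ellipse_candidates",
    "align_segmentation",
    "deconvolve",
]


@dataclass
class Trace:
    """A fluorescence time series sampled at ``rate`` samples/s."""

    values: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise DataError("trace contains NaN or Inf")
        if self.rate <= 0:
            raise DataError("trace rate must be positive")

    def __len__(self) -> int:
        return self.values.size


# ---------------------------------------------------------------------------
# Trace statistics
# ---------------------------------------------------------------------------

def _values(trace) -> np.ndarray:
    return trace.values if isinstance(trace, Trace) else np.asarray(trace, dtype=float).ravel()


def snr(trace) -> float:
    """Peak-over-noise SNR of a trace.

    Raises DegenerateTraceError when no value lies strictly below the 25th
    percentile (constant trace) or the noise sample has zero spread.
    """
    f = _values(trace)
    if f.size < 2:
        raise DegenerateTraceError("trace too short for an SNR estimate")
    p25 = np.percentile(f, 25)
    f25 = f[f < p25]
    if f25.size == 0:
        raise DegenerateTraceError("empty sub-25th-percentile sample (constant trace?)")
    sd = f25.std()  # population std
    if sd == 0:
        raise DegenerateTraceError("zero spread in the sub-25th-percentile sample")
    return float((f.max() - f25.mean()) / sd)


def snr_or_none(trace) -> Optional[float]:
    """SNR, or None for degenerate traces (used for sorting candidate pixels)."""
    try:
        return snr(trace)
    except DegenerateTraceError:
        return None


def dff(trace: Trace) -> Trace:
    """Normalised fluorescence (f - F0)/F0 with F0 = mean of the sub-median values."""
    f = _values(trace)
    med = np.percentile(f, 50)
    f50 = f[f < med]
    if f50.size == 0:
        raise DegenerateTraceError("empty sub-median sample (constant trace?)")
    f0 = f50.mean()
    if f0 <= 0:
        raise DegenerateTraceError(f"non-positive baseline F0 = {f0}")
    return Trace((f - f0) / f0, rate=trace.rate if isinstance(trace, Trace) else 1.0)


# ---------------------------------------------------------------------------
# Projections
# ---------------------------------------------------------------------------

def compute_projections(movie: RasterMovie) -> dict[str, np.ndarray]:
    """Average, max-min and local-correlation projections of a movie.

    The correlation projection is the per-pixel mean Pearson correlation of its
    trace with the traces of its 8-connected neighbours (border pixels use the
    available neighbours); correlations undefined because a trace is constant
    count as 0.
    """
    frames = movie.frames
    T = frames.shape[0]
    if T < 2:
        raise DataError("projections require at least 2 frames")
    avg = frames.mean(axis=0)
    max_min = frames.max(axis=0) - frames.min(axis=0)

    z = frames - frames.mean(axis=0)
    sd = z.std(axis=0)
    ok = sd > 0
    z = np.divide(z, sd, out=np.zeros_like(z), where=ok)
    # mean corr with 8 neighbours: corr(a,b) = dot(z_a, z_b)/T; zeros encode
    # undefined (constant) traces
    H, W = avg.shape
    corr_sum = np.zeros((H, W))
    count = np.zeros((H, W))
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            ys = slice(max(0, dy), H + min(0, dy))
            xs = slice(max(0, dx), W + min(0, dx))
            ysn = slice(max(0, -dy), H + min(0, -dy))
            xsn = slice(max(0, -dx), W + min(0, -dx))
            corr_sum[ys, xs] += (z[:, ys, xs] * z[:, ysn, xsn]).sum(axis=0) / T
            count[ys, xs] += 1
    corr = corr_sum / count
    return {"average": avg, "max_min": max_min, "correlation": corr}


# ---------------------------------------------------------------------------
# Registration
# ---------------------------------------------------------------------------

@dataclass
class RegistrationResult:
    """Per-frame correction shifts, the registered movie and its template."""

    shifts: np.ndarray          # [T, 2] (dy, dx), the correction applied to each frame
    registered: RasterMovie
    template: np.ndarray
    patch_shifts: Optional[np.ndarray] = None  # [T, gy, gx, 2] in patch mode


def _xcorr_shift(image: np.ndarray, template: np.ndarray, max_shift: int) -> np.ndarray:
    """Displacement (dy, dx) of ``image`` relative to ``template``.

    Overlap-masked normalised cross-correlation (each lag is scored by the
    Pearson correlation over the actually overlapping region), evaluated on
    the integer grid within ``max_shift`` and refined to subpixel with
    quadratic peak interpolation.
    """
    H, W = image.shape
    m = int(min(max_shift, H - 1, W - 1))
    if m < 1 or np.ptp(image) == 0 or np.ptp(template) == 0:
        return np.zeros(2)

    def xc(p, q):
        return signal.fftconvolve(p, q[::-1, ::-1], mode="full")

    one = np.ones_like(image)
    n = np.maximum(xc(one, one), 1e-9)
    sa = xc(image, one)
    sb = xc(one, template)
    num = xc(image, template) - sa * sb / n
    da = np.maximum(xc(image ** 2, one) - sa ** 2 / n, 0.0)
    db = np.maximum(xc(one, template ** 2) - sb ** 2 / n, 0.0)
    den = np.sqrt(da * db)
    c = np.where(den > 1e-9, num / np.maximum(den, 1e-9), 0.0)
    win = c[H - 1 - m: H + m, W - 1 - m: W + m]
    iy, ix = np.unravel_index(np.argmax(win), win.shape)

    def refine(i, nn, get) -> float:
        if i == 0 or i == nn - 1:
            return 0.0
        cm1, c0, cp1 = get(i - 1), get(i), get(i + 1)
        denom = cm1 - 2 * c0 + cp1
        if denom >= 0:
            return 0.0
        return float(np.clip(0.5 * (cm1 - cp1) / denom, -0.5, 0.5))

    sub_y = refine(iy, win.shape[0], lambda i: win[i, ix])
    sub_x = refine(ix, win.shape[1], lambda i: win[iy, i])
    d = np.array([iy - m + sub_y, ix - m + sub_x])
    return np.clip(d, -max_shift, max_shift)


def _patch_grid(H: int, W: int, grid: tuple[int, int]) -> list[tuple[slice, slice, float, float]]:
    """Overlapping patches (~50% overlap): patch size 2*L/(g+1), centers evenly spaced."""
    gy, gx = grid
    ph = max(4, int(round(2 * H / (gy + 1))))
    pw = max(4, int(round(2 * W / (gx + 1))))
    out = []
    for i in range(gy):
        for j in range(gx):
            cy = (i + 1) * H / (gy + 1)
            cx = (j + 1) * W / (gx + 1)
            r0 = int(np.clip(round(cy - ph / 2), 0, H - ph))
            c0 = int(np.clip(round(cx - pw / 2), 0, W - pw))
            out.append((slice(r0, r0 + ph), slice(c0, c0 + pw), cy, cx))
    return out


def register_raster(movie: RasterMovie, mode: str = "rigid", n_template: int = 10,
                    max_shift: int = 10, patch_grid: tuple[int, int] = (4, 4)
                    ) -> RegistrationResult:
    """Register a movie to the temporal mean of its first ``n_template`` frames.

    ``rigid`` estimates one cross-correlation shift per frame (quadratic
    subpixel refinement, capped at ``max_shift``); ``patch`` estimates a rigid
    shift per patch of an overlapping grid and blends a per-pixel shift field
    bilinearly between patch centers.  Frames are resampled with zero fill at
    the borders; the returned shifts are the corrections applied.
    """
    frames = movie.frames
    T, H, W = frames.shape
    if n_template < 1 or n_template > T:
        raise ConfigError(f"n_template must be in [1, {T}]")
    if max_shift >= min(H, W) / 2:
        raise ConfigError("max_shift must be below half the smallest FOV dimension")
    if mode not in ("rigid", "patch"):
        raise ConfigError(f"unknown registration mode {mode!r}")
    template = frames[:n_template].mean(axis=0)

    shifts = np.zeros((T, 2))
    registered = np.empty_like(frames)
    patch_shifts = None

    if mode == "rigid":
        for t in range(T):
            d = _xcorr_shift(frames[t], template, max_shift)
            shifts[t] = -d
            registered[t] = ndimage.shift(frames[t], shifts[t], order=1, cval=0.0)
    else:
        patches = _patch_grid(H, W, patch_grid)
        gy, gx = patch_grid
        patch_shifts = np.zeros((T, gy, gx, 2))
        cys = np.array(sorted({p[2] for p in patches}))
        cxs = np.array(sorted({p[3] for p in patches}))
        yy, xx = np.mgrid[0:H, 0:W]
        Wy = _bilinear_weights(np.arange(H, dtype=float), cys)   # [H, gy]
        Wx = _bilinear_weights(np.arange(W, dtype=float), cxs)   # [W, gx]
        for t in range(T):
            for k, (ys, xs, cy, cx) in enumerate(patches):
                i, j = divmod(k, gx)
                d = _xcorr_shift(frames[t][ys, xs], template[ys, xs],
                                 min(max_shift, (ys.stop - ys.start) // 2 - 1))
                patch_shifts[t, i, j] = -d
            # separable bilinear blend of patch-center shifts (clamped at edges)
            dy_field = Wy @ patch_shifts[t, :, :, 0] @ Wx.T
            dx_field = Wy @ patch_shifts[t, :, :, 1] @ Wx.T
            shifts[t] = [dy_field.mean(), dx_field.mean()]
            registered[t] = ndimage.map_coordinates(
                frames[t], [yy - dy_field, xx - dx_field], order=1, cval=0.0)

    return RegistrationResult(shifts=shifts,
                              registered=RasterMovie(registered, movie.meta),
                              template=template, patch_shifts=patch_shifts)


def _bilinear_weights(pos: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """[len(pos), len(centers)] linear interpolation weights, clamped at the ends."""
    n = len(centers)
    w = np.zeros((len(pos), n))
    idx = np.clip(np.searchsorted(centers, pos) - 1, 0, n - 2)
    x0 = centers[idx]
    x1 = centers[idx + 1]
    frac = np.clip((pos - x0) / (x1 - x0), 0, 1)
    w[np.arange(len(pos)), idx] = 1 - frac
    w[np.arange(len(pos)), idx + 1] += frac
    return w


# ---------------------------------------------------------------------------
# SNR-maximising pixel selection
# ---------------------------------------------------------------------------

def snr_maximize_pixels(movie: RasterMovie,
                        candidate_pixels: Sequence[tuple[int, int]]
                        ) -> list[tuple[int, int]]:
    """Select the pixel subset maximising the pooled-trace SNR.

    Candidates are sorted by decreasing single-pixel SNR (ties broken by
    (row, col) ascending, degenerate traces last); the SNR of the k-pixel mean
    trace is evaluated for every prefix k = 1..N and the shortest prefix
    achieving the maximum is returned.
    """
    cands = [(int(r), int(c)) for r, c in candidate_pixels]
    if not cands:
        raise DataError("no candidate pixels")
    traces = np.array([movie.frames[:, r, c] for r, c in cands])
    pixel_snr = np.array([s if (s := snr_or_none(tr)) is not None else -np.inf
                          for tr in traces])
    if not np.any(np.isfinite(pixel_snr)):
        raise DegenerateTraceError("all candidate pixels have degenerate traces")
    rows = np.array([p[0] for p in cands])
    cols = np.array([p[1] for p in cands])
    order = np.lexsort((cols, rows, -pixel_snr))
    sorted_traces = traces[order]
    prefix_means = np.cumsum(sorted_traces, axis=0) / np.arange(1, len(cands) + 1)[:, None]
    best_k, best_snr = None, -np.inf
    for k in range(1, len(cands) + 1):
        s = snr_or_none(prefix_means[k - 1])
        if s is not None and s > best_snr:
            best_k, best_snr = k, s
    if best_k is None:
        raise DegenerateTraceError("every prefix trace is degenerate")
    return [cands[i] for i in order[:best_k]]


# ---------------------------------------------------------------------------
# Manual-segmentation pixel candidates
# ---------------------------------------------------------------------------

def ellipse_candidates(contour=None, bbox=None,
                       fov_shape: tuple[int, int] = None) -> list[tuple[int, int]]:
    """Candidate pixels inside an ellipse fitted to a drawn contour, or inside
    a bounding box ``(row0, col0, height, width)``.  Pixel centers strictly
    inside (<= boundary) count; results are clipped to the FOV.
    """
    if fov_shape is None:
        raise ConfigError("fov_shape is required")
    H, W = fov_shape
    if bbox is not None:
        r0, c0, h, w = bbox
        if h < 1 or w < 1:
            raise DataError("bbox must have positive size")
        return [(r, c) for r in range(max(0, r0), min(H, r0 + h))
                for c in range(max(0, c0), min(W, c0 + w))]
    pts = np.asarray(contour, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 5:
        raise DataError("ellipse fit needs at least 5 contour points")
    # collinearity check: rank of centered points
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise DataError("degenerate (collinear) contour")
    # EllipseModel works in (x, y); feed (col, row)
    if hasattr(EllipseModel, "from_estimate"):
        model = EllipseModel.from_estimate(pts[:, ::-1])
        if not model:
            raise DataError("ellipse fit failed")
        (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    else:  # scikit-image < 0.26
        model = EllipseModel()
        if not model.estimate(pts[:, ::-1]):
            raise DataError("ellipse fit failed")
        xc, yc, a, b, theta = model.params
    rr, cc = np.mgrid[0:H, 0:W]
    x = cc - xc
    y = rr - yc
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0 + 1e-6   # tolerate fit round-off
    return [(int(r), int(c)) for r, c in np.argwhere(inside)]


# ---------------------------------------------------------------------------
# Longitudinal segmentation alignment
# ---------------------------------------------------------------------------

def _rotate_image(img: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the FOV center (bilinear, zero fill).  Positive angles
    rotate coordinates counter-clockwise in (row, col) space."""
    if angle_deg == 0:
        return img
    H, W = img.shape
    cy, cx = (H - 1) / 2, (W - 1) / 2
    th = np.deg2rad(angle_deg)
    ct, st = np.cos(th), np.sin(th)
    yy, xx = np.mgrid[0:H, 0:W]
    y = yy - cy
    x = xx - cx
    # inverse mapping: source coords for each output pixel
    ys = ct * y + st * x + cy
    xs = -st * y + ct * x + cx
    return ndimage.map_coordinates(img, [ys, xs], order=1, cval=0.0)


def align_segmentation(seg: Segmentation, source_projection: np.ndarray,
                       target_projection: np.ndarray,
                       shift_range: int = 20, angle_range: float = 10.0,
                       angle_step: float = 0.5
                       ) -> tuple[Segmentation, dict]:
    """Align ROIs from a previous session onto a new FOV.

    Grid search over integer shifts (±``shift_range``, evaluated for all shifts
    at once via circular cross-correlation) × rotation angles
    (±``angle_range`` in steps of ``angle_step`` degrees about the FOV
    center): the rigid transform minimising the MSE between the transformed
    source projection and the target projection is applied to all ROI pixels
    (nearest-pixel rounding, out-of-FOV pixels dropped).

    Returns the transformed segmentation and a report dict with the chosen
    ``shift``, ``angle`` and ``mse``.
    """
    src = np.asarray(source_projection, dtype=float)
    tgt = np.asarray(target_projection, dtype=float)
    if src.shape != tgt.shape:
        raise DataError("projections must share a shape")
    if shift_range < 0 or angle_range < 0 or angle_step <= 0:
        raise ConfigError("empty alignment search range")
    H, W = src.shape
    angles = np.arange(-angle_range, angle_range + 1e-9, angle_step) if angle_range > 0 \
        else np.array([0.0])
    dy = np.fft.fftfreq(H, 1 / H).astype(int)
    dx = np.fft.fftfreq(W, 1 / W).astype(int)
    valid = (np.abs(dy)[:, None] <= shift_range) & (np.abs(dx)[None, :] <= shift_range)
    Ft = np.conj(np.fft.fft2(tgt))
    sum_t2 = (tgt ** 2).sum()
    best = None
    for ang in angles:
        rot = _rotate_image(src, ang)
        # MSE of roll(rot, s) vs tgt: (sum rot^2 + sum tgt^2 - 2*circcorr(-s)) / N
        cc = np.real(np.fft.ifft2(np.fft.fft2(rot) * Ft))
        mse = (np.sum(rot ** 2) + sum_t2 - 2 * cc) / (H * W)
        mse = np.where(valid, mse, np.inf)
        iy, ix = np.unravel_index(np.argmin(mse), mse.shape)
        if best is None or mse[iy, ix] < best[0]:
            best = (float(mse[iy, ix]), (-int(dy[iy]), -int(dx[ix])), float(ang))
    mse_val, (sdy, sdx), angle = best

    cy, cx = (H - 1) / 2, (W - 1) / 2
    th = np.deg2rad(angle)
    ct, st = np.cos(th), np.sin(th)
    new_rois = []
    for roi in seg.rois:
        y = roi.pixels[:, 0] - cy
        x = roi.pixels[:, 1] - cx
        # forward map matching _rotate_image's inverse mapping
        ny = np.rint(ct * y - st * x + cy + sdy).astype(int)
        nx = np.rint(st * y + ct * x + cx + sdx).astype(int)
        keep = (ny >= 0) & (ny < H) & (nx >= 0) & (nx < W)
        if not np.any(keep):
            continue
        px = np.column_stack([ny[keep], nx[keep]])
        px, idx = np.unique(px, axis=0, return_index=True)
        new_rois.append(ROI(id=roi.id, pixels=px, weights=roi.weights[keep][idx]))
    out = Segmentation(fov_shape=(H, W), rois=new_rois)
    return out, {"shift": (sdy, sdx), "angle": angle, "mse": mse_val}


# ---------------------------------------------------------------------------
# Deconvolution
# ---------------------------------------------------------------------------

def ar_order_for_rate(rate_hz: float) -> int:
    """Autoregressive model order: 1 below 2 Hz sampling, 2 otherwise."""
    return 1 if rate_hz < 2.0 else 2


def _yule_walker(f: np.ndarray, p: int) -> np.ndarray:
    """AR(p) coefficients from the centered sample autocovariance."""
    fc = f - f.mean()
    n = fc.size
    r = np.array([fc[: n - k] @ fc[k:] for k in range(p + 1)]) / n
    if r[0] <= 1e-12 * max(1.0, float(np.abs(f).max()) ** 2):
        return np.zeros(p)
    return solve_toeplitz(r[:p], r[1: p + 1])


def deconvolve(dff_trace: Trace, order: Optional[int] = None
               ) -> tuple[Trace, Trace, np.ndarray]:
    """Deconvolve a normalised calcium trace with an AR(p) kernel.

    The order defaults to the acquisition-rate rule (AR(1) below 2 Hz, AR(2)
    otherwise).  Coefficients come from the Yule-Walker equations on the
    centered autocovariance; the inferred activity is the rectified prediction
    error  a(t) = max(0, f(t) - sum_i g_i f(t-i))  (zero-padded start) and the
    denoised trace re-convolves the activity with the AR kernel.

    Returns (denoised, activity, ar_coeffs).
    """
    f = _values(dff_trace)
    rate = dff_trace.rate
    p = ar_order_for_rate(rate) if order is None else int(order)
    if p not in (1, 2):
        raise ConfigError("AR order must be 1 or 2")
    if f.size < 3 * p:
        raise DataError(f"trace of {f.size} samples too short for AR({p}) fit")
    gamma = _yule_walker(f, p)
    pred = np.zeros_like(f)
    for i, g in enumerate(gamma, start=1):
        pred[i:] += g * f[:-i]
    activity = np.maximum(0.0, f - pred)
    denoised = signal.lfilter([1.0], np.concatenate([[1.0], -gamma]), activity)
    return Trace(denoised, rate), Trace(activity, rate), gamma
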
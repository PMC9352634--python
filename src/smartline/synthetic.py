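"""Ground-truth simulator for raster movies and SLS recordings.

The simulated session mimics a GCaMP-expressing cortical field of view: disk
shaped somata with smooth per-pixel gain, Poisson spike trains filtered by a
stable AR(2) calcium kernel, a spatially smooth neuropil field driven by a
shared slow signal (plus small per-ROI jitter), a spatially uniform slow
background series, a constant photon offset, additive Gaussian shot-like
noise, and rigid planar motion (a random-walk drift and an optional abrupt
large shift).  Within-line time is collapsed: all pixels of a line share one
timestamp.  Everything is reproducible from the scene seed (numpy
``default_rng`` PCG64 streams with fixed draw order; the noise field is drawn
as one full-FOV field per time index so that the raster and line-scan
renderers agree exactly on trajectory coordinates).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage, signal

from .errors import ConfigError, DataError
from .io import (AcquisitionMetadata, RasterMovie, ROI, Segmentation,
                 SLSRecording, SLSTrajectory)

__all__ = [
    "SceneConfig",
    "MotionConfig",
    "GroundTruth",
    "make_scene",
    "simulate_traces",
    "render_raster",
    "render_sls",
    "make_artifact_recording",
]


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions of a simulated session.

    Defaults emulate a small GCaMP6s-like field: 6 somata of radius 3 px in an
    80x80 FOV, 0.3 Hz spiking filtered by the AR(2) kernel (1.6, -0.64)
    (~ slow-indicator rise/decay at tens of Hz sampling), strong shared
    neuropil and background (the deep-cortex regime the decontamination steps
    target), static anatomical texture, and Gaussian noise.
    """

    fov_shape: tuple[int, int] = (80, 80)
    n_rois: int = 6
    roi_radius: float = 3.0
    spike_rate: float = 0.3          # Hz
    kernel: tuple[float, float] = (1.6, -0.64)
    spike_amplitude: float = 60.0
    background_amplitude: float = 20.0
    neuropil_amplitude: float = 28.0
    noise_sd: float = 4.0
    photon_offset: float = 40.0
    soma_baseline: float = 40.0      # resting somatic brightness (indicator-filled)
    texture_amplitude: float = 20.0  # static anatomical contrast (vessels, processes)
    psf_sigma: float = 0.8           # px, optical blur of the somatic footprint
    seed: int = 0

    def __post_init__(self) -> None:
        g1, g2 = self.kernel
        roots = np.roots([1.0, -g1, -g2])
        if np.any(np.abs(roots) >= 1.0):
            raise ConfigError("AR kernel is unstable (root on/outside the unit circle)")
        for name in ("spike_rate", "background_amplitude", "neuropil_amplitude",
                     "noise_sd", "photon_offset", "spike_amplitude",
                     "texture_amplitude", "soma_baseline"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass(frozen=True)
class MotionConfig:
    """Rigid planar motion: random-walk drift plus an optional abrupt shift
    (line/frame index, (dy, dx)) modelling a large artefact (> 4 px)."""

    drift_sd: float = 0.0            # px per sqrt(line)
    large_shift: Optional[tuple[int, tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.drift_sd < 0:
            raise ConfigError("drift_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything the simulator knows: the segmentation, per-ROI spike trains
    and noiseless somatic traces, the background and per-ROI neuropil series,
    and (after rendering) the motion series."""

    config: SceneConfig
    segmentation: Segmentation
    roi_gain: np.ndarray              # [H, W], somatic gain inside ROIs, 0 elsewhere
    roi_of_pixel: np.ndarray          # [H, W] int, ROI id per pixel (0 = none)
    neuropil_field: np.ndarray        # [H, W]
    static_texture: np.ndarray = None # [H, W], time-invariant anatomical contrast
    spikes: Optional[np.ndarray] = None           # [n_rois, T]
    somatic: Optional[np.ndarray] = None          # [n_rois, T] noiseless traces
    background: Optional[np.ndarray] = None       # [T]
    neuropil: Optional[np.ndarray] = None         # [n_rois, T]
    neuropil_shared: Optional[np.ndarray] = None  # [T]
    rate_hz: Optional[float] = None
    motion: Optional[np.ndarray] = None           # [T, 2] (dy, dx)

    @property
    def n_samples(self) -> int:
        return 0 if self.background is None else self.background.size


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def make_scene(cfg: SceneConfig = SceneConfig()) -> tuple[np.ndarray, Segmentation, GroundTruth]:
    """Place disk-shaped somata in the FOV and build the static fields.

    Returns (static scene image at rest, segmentation, ground-truth skeleton).
    ROI centers are rejection-sampled with a minimum separation of
    ``2 * roi_radius + 3`` px and a margin keeping disks inside the FOV.
    """
    H, W = cfg.fov_shape
    rng = _rng(cfg.seed, 1)
    margin = int(np.ceil(cfg.roi_radius)) + 1
    min_sep = 2 * cfg.roi_radius + 3
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(centers) < cfg.n_rois:
        tries += 1
        if tries > 5000:
            raise DataError(f"could not place {cfg.n_rois} ROIs of radius "
                            f"{cfg.roi_radius} in a {H}x{W} FOV")
        r = int(rng.integers(margin, H - margin))
        c = int(rng.integers(margin, W - margin))
        if all(np.hypot(r - rr, c - cc) >= min_sep for rr, cc in centers):
            centers.append((r, c))

    yy, xx = np.mgrid[0:H, 0:W]
    roi_gain = np.zeros((H, W))
    roi_of_pixel = np.zeros((H, W), dtype=int)
    rois: list[ROI] = []
    gain_field = ndimage.gaussian_filter(rng.normal(size=(H, W)), 4.0)
    gf_sd = gain_field.std()
    gain_field = 1.0 + 0.2 * (gain_field / gf_sd if gf_sd > 0 else gain_field)
    for k, (r, c) in enumerate(centers, start=1):
        disk = (yy - r) ** 2 + (xx - c) ** 2 <= cfg.roi_radius ** 2
        roi_gain[disk] = gain_field[disk]
        px = np.argwhere(disk)
        rois.append(ROI(id=k, pixels=px, weights=np.ones(px.shape[0])))
    seg = Segmentation(fov_shape=(H, W), rois=rois)
    if cfg.psf_sigma > 0:
        # optical blur: somatic fluorescence bleeds ~1 px beyond the anatomical disk
        roi_gain = ndimage.gaussian_filter(roi_gain, cfg.psf_sigma)
    lit = roi_gain > 1e-3
    if np.any(lit):
        ctr = np.array(centers, dtype=float)
        ly, lx = np.nonzero(lit)
        d = (ly[:, None] - ctr[None, :, 0]) ** 2 + (lx[:, None] - ctr[None, :, 1]) ** 2
        roi_of_pixel[ly, lx] = np.argmin(d, axis=1) + 1

    np_field = ndimage.gaussian_filter(rng.normal(size=(H, W)), 6.0)
    np_field -= np_field.min()
    if np_field.max() > 0:
        np_field /= np_field.max()
    np_field = 0.3 + 0.7 * np_field           # everywhere positive, smooth

    texture = ndimage.gaussian_filter(rng.normal(size=(H, W)), 1.5)
    tsd = texture.std()
    z = texture / tsd if tsd > 0 else texture
    # mean ~ amplitude, sd ~ amplitude/2: tissue dimmer than indicator-filled somata
    texture = np.clip(cfg.texture_amplitude * (1.0 + 0.5 * z), 0.0, None)
    # somata occlude the anatomical texture of the surrounding tissue
    texture *= np.clip(1.0 - roi_gain, 0.0, 1.0)

    gt = GroundTruth(config=cfg, segmentation=seg, roi_gain=roi_gain,
                     roi_of_pixel=roi_of_pixel, neuropil_field=np_field,
                     static_texture=texture)
    scene = cfg.photon_offset + texture
    return scene, seg, gt


def simulate_traces(gt: GroundTruth, duration_s: float, rate_hz: float) -> GroundTruth:
    """Draw spike trains and temporal series for ``duration_s`` at ``rate_hz``.

    Somatic traces filter Poisson spikes with the AR(2) kernel; the background
    and the shared neuropil are unit-variance smoothed Gaussian noise scaled by
    their amplitudes; each ROI's neuropil adds 20% local jitter to the shared
    signal.
    """
    cfg = gt.config
    T = int(round(duration_s * rate_hz))
    if T < 4:
        raise ConfigError("duration too short")
    n = gt.segmentation.n_rois
    rng = _rng(cfg.seed, 2)
    g1, g2 = cfg.kernel
    spikes = rng.poisson(cfg.spike_rate / rate_hz, size=(max(n, 1), T)).astype(float)
    if n == 0:
        spikes = spikes[:0]
    somatic = np.array([
        signal.lfilter([1.0], [1.0, -g1, -g2], cfg.spike_amplitude * s)
        for s in spikes]) if n else np.empty((0, T))

    def slow(series_rng, sigma=rate_hz):  # ~1 s correlation time
        x = ndimage.gaussian_filter1d(series_rng.normal(size=T), sigma)
        sd = x.std()
        return x / sd if sd > 0 else x

    bg = slow(rng) * cfg.background_amplitude
    shared = slow(rng)
    neuropil = np.array([
        (shared + 0.2 * slow(rng)) * cfg.neuropil_amplitude for _ in range(n)
    ]) if n else np.empty((0, T))

    gt.spikes = spikes
    gt.somatic = somatic
    gt.background = bg
    gt.neuropil_shared = shared * cfg.neuropil_amplitude
    gt.neuropil = neuropil
    gt.rate_hz = rate_hz
    return gt


def _motion_series(gt: GroundTruth, motion: MotionConfig, n_steps: int) -> np.ndarray:
    rng = _rng(gt.config.seed, 3)
    steps = rng.normal(0.0, motion.drift_sd, size=(n_steps, 2)) if motion.drift_sd > 0 \
        else np.zeros((n_steps, 2))
    series = np.cumsum(steps, axis=0)
    if motion.large_shift is not None:
        t0, (dy, dx) = motion.large_shift
        series[t0:] += np.array([dy, dx])
    return series


def _frame_values(gt: GroundTruth, t: int, coords_r: np.ndarray, coords_c: np.ndarray,
                  shift: np.ndarray) -> np.ndarray:
    """Noiseless scene values at time t, sampled at (coords - shift) with
    bilinear interpolation (tissue displaced by ``shift``)."""
    cfg = gt.config
    ys = coords_r - shift[0]
    xs = coords_c - shift[1]
    pts = np.vstack([ys, xs])
    gain = ndimage.map_coordinates(gt.roi_gain, pts, order=1, cval=0.0)
    tex = ndimage.map_coordinates(gt.static_texture, pts, order=1, cval=0.0)
    which = ndimage.map_coordinates(gt.roi_of_pixel.astype(float), pts, order=0, cval=0.0)
    npf = ndimage.map_coordinates(gt.neuropil_field, pts, order=1, cval=0.0)
    soma = np.zeros_like(gain)
    neuro = gt.neuropil_shared[t] * np.ones_like(gain)
    for j, roi in enumerate(gt.segmentation.rois):
        inside = which == roi.id
        if np.any(inside):
            soma[inside] = gain[inside] * (cfg.soma_baseline + gt.somatic[j, t])
            neuro[inside] = gt.neuropil[j, t]
    return cfg.photon_offset + tex + soma + npf * neuro + gt.background[t]


def render_raster(gt: GroundTruth, motion: MotionConfig = MotionConfig(),
                  n_frames: Optional[int] = None) -> RasterMovie:
    """Render the session as a raster movie (one frame per time sample)."""
    if gt.background is None:
        raise DataError("call simulate_traces before rendering")
    cfg = gt.config
    H, W = cfg.fov_shape
    T = gt.n_samples if n_frames is None else min(n_frames, gt.n_samples)
    series = _motion_series(gt, motion, T)
    gt.motion = series
    yy, xx = np.mgrid[0:H, 0:W]
    rr = yy.ravel().astype(float)
    cc = xx.ravel().astype(float)
    noise_rng = _rng(cfg.seed, 4)
    frames = np.empty((T, H, W))
    for t in range(T):
        vals = _frame_values(gt, t, rr, cc, series[t]).reshape(H, W)
        noise = noise_rng.normal(0.0, cfg.noise_sd, size=(H, W)) if cfg.noise_sd > 0 \
            else 0.0
        frames[t] = np.maximum(0.0, vals + noise)
    period = 1.0 / gt.rate_hz
    meta = AcquisitionMetadata(pixel_size=1.0, frame_period=period,
                               line_period=period, dwell_time=1.0)
    return RasterMovie(frames=frames, meta=meta)


def render_sls(gt: GroundTruth, traj: SLSTrajectory,
               motion: MotionConfig = MotionConfig(),
               n_lines: Optional[int] = None) -> SLSRecording:
    """Render the session as an SLS recording along ``traj``.

    Each line samples the motion-shifted scene at the trajectory coordinates at
    that line's time; the noise stream matches ``render_raster`` (a full-FOV
    field per time index), so the two renderers agree exactly on trajectory
    coordinates under identical motion and seed.
    """
    if gt.background is None:
        raise DataError("call simulate_traces before rendering")
    cfg = gt.config
    H, W = cfg.fov_shape
    if (traj.coords[:, 0].min() < 0 or traj.coords[:, 1].min() < 0
            or traj.coords[:, 0].max() >= H or traj.coords[:, 1].max() >= W):
        raise DataError("trajectory falls outside the scene FOV")
    T = gt.n_samples if n_lines is None else min(n_lines, gt.n_samples)
    series = _motion_series(gt, motion, T)
    gt.motion = series
    rr = traj.coords[:, 0].astype(float)
    cc = traj.coords[:, 1].astype(float)
    noise_rng = _rng(cfg.seed, 4)
    lines = np.empty((T, traj.n_pixels))
    for t in range(T):
        vals = _frame_values(gt, t, rr, cc, series[t])
        if cfg.noise_sd > 0:
            noise = noise_rng.normal(0.0, cfg.noise_sd, size=(H, W))
            vals = vals + noise[traj.coords[:, 0], traj.coords[:, 1]]
        lines[t] = np.maximum(0.0, vals)
    ts = np.arange(T) * traj.line_period
    return SLSRecording(lines=lines, timestamps=ts, trajectory=traj)


# ---------------------------------------------------------------------------
# Purpose-built artefact recordings (large-artefact detector conditions)
# ---------------------------------------------------------------------------

def make_artifact_recording(traj: SLSTrajectory, n_lines: int, *, seed: int,
                            artifact_line: Optional[int] = None,
                            signal_sd: float = 10.0, noise_sd: float = 1.0,
                            offset: float = 50.0) -> SLSRecording:
    """A recording whose PC1 is an AR(2)-consistent shared signal, optionally
    switching every pixel to independent white noise at ``artifact_line``
    (the whole-trajectory decorrelating event the large-artefact detector is
    built for)."""
    rng = np.random.default_rng([seed, 7])
    shared = signal.lfilter([1.0], [1.0, -1.6, 0.64],
                            rng.normal(size=n_lines))
    sd = shared.std()
    shared = shared / (sd if sd > 0 else 1.0) * signal_sd
    m = traj.n_pixels
    loadings = 0.5 + rng.random(m)
    lines = offset + shared[:, None] * loadings[None, :] \
        + rng.normal(0.0, noise_sd, size=(n_lines, m))
    if artifact_line is not None:
        post = n_lines - artifact_line
        lines[artifact_line:] = offset + rng.normal(
            0.0, signal_sd, size=(post, m))
    ts = np.arange(n_lines) * traj.line_period
    return SLSRecording(lines=np.maximum(lines, 0.0), timestamps=ts, trajectory=traj)
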
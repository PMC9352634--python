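"""Processing of smart-line-scan (SLS) recordings.

The stages mirror the acquisition-to-traces pipeline for line recordings:

1. classify every trajectory pixel against a reference segmentation by its
   Euclidean distance to each ROI (ROI <= 1 px, outer ring (1, 2] px, surround
   (2, 4] px, background > 4 px from all ROIs; pixels claimed by two ROIs are
   discarded);
2. detect large motion artefacts from the first principal component of the
   recording: PC1 scores are fitted with an AR(2) model and a trailing 10 s
   sliding correlation between scores and fit below 0.3 crops the recording;
3. subtract a shared background: rank-1 PCA reconstruction of the
   background-pixel activity, averaged across pixels, scaled by 0.7 and
   subtracted from every pixel (negatives clipped to zero);
4. correct small/local motion line by line, either by re-ranking each ROI's
   candidate pool by forward-window SNR, or by registering the reference-box
   image sequence and shifting the ROI footprints accordingly;
5. decontaminate neuropil locally (surround mean x 0.7 subtracted per ROI) or
   globally (rank-1 PCA of the ROI signals subtracted from each ROI);
6. extract per-ROI traces, deconvolve, and score the pipeline by the change in
   trace SNR and in mean pairwise correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ConfigError, DataError, DegenerateTraceError
from .io import RasterMovie, Segmentation, SLSRecording, SLSTrajectory, AcquisitionMetadata
from . import raster as rp
from .raster import Trace

__all__ = [
    "PixelClassification",
    "ArtifactReport",
    "LineAssignment",
    "TraceSet",
    "classify_pixels",
    "detect_large_artifact",
    "subtract_background",
    "correct_motion_snr",
    "correct_motion_refbox",
    "subtract_neuropil_local",
    "subtract_neuropil_global",
    "extract_traces",
    "deconvolve_sls",
    "quality_metrics",
    "run_pipeline",
]

# distance bands (px) for pixel classification, distances between pixel centers
ROI_BAND = 1.0
OUTER_RING_BAND = 2.0
SURROUND_BAND = 4.0


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class PixelClassification:
    """Per-trajectory-pixel class labels.

    ``category`` holds one of ``roi``, ``outer_ring``, ``surround``,
    ``background``, ``discarded``; ``roi_id`` the assigned ROI (or None) and
    ``distance`` the Euclidean distance to that ROI's nearest pixel.
    """

    category: list[str]
    roi_id: list[Optional[int]]
    distance: np.ndarray

    def indices(self, category: str, roi_id: Optional[int] = None) -> np.ndarray:
        sel = [i for i, c in enumerate(self.category)
               if c == category and (roi_id is None or self.roi_id[i] == roi_id)]
        return np.array(sel, dtype=int)

    def pool_indices(self, roi_id: int) -> np.ndarray:
        """ROI + outer-ring + surround pixels of one ROI (the motion-correction pool)."""
        sel = [i for i, (c, k) in enumerate(zip(self.category, self.roi_id))
               if k == roi_id and c in ("roi", "outer_ring", "surround")]
        return np.array(sel, dtype=int)

    @property
    def roi_ids(self) -> list[int]:
        return sorted({k for k in self.roi_id if k is not None})


@dataclass
class ArtifactReport:
    """Diagnostics of the large-artefact detector."""

    pc1_scores: np.ndarray
    ar2_fit: np.ndarray
    sliding_corr: np.ndarray      # NaN before the first full window
    crop_index: Optional[int]
    threshold: float
    window_s: float


@dataclass
class LineAssignment:
    """Per-line, per-ROI sets of trajectory-pixel indices counted as the ROI.

    ``assigned[k]`` is an ``[n_lines, n_k]`` integer array; ``pool[k]`` the
    ROI's full candidate pool (ROI + outer ring + surround pixel indices).
    """

    assigned: dict[int, np.ndarray]
    pool: dict[int, np.ndarray]
    n_lines: int

    def unassigned(self, roi_id: int, line: int) -> np.ndarray:
        a = set(self.assigned[roi_id][line].tolist())
        return np.array([i for i in self.pool[roi_id] if i not in a], dtype=int)

    @classmethod
    def static(cls, cls_: PixelClassification, n_lines: int) -> "LineAssignment":
        """The identity assignment: every line uses the classification's ROI pixels."""
        assigned, pool = {}, {}
        for k in cls_.roi_ids:
            idx = cls_.indices("roi", k)
            if idx.size == 0:
                raise DataError(f"ROI {k} has no trajectory pixels classified as ROI")
            assigned[k] = np.tile(idx, (n_lines, 1))
            pool[k] = cls_.pool_indices(k)
        return cls(assigned=assigned, pool=pool, n_lines=n_lines)


@dataclass
class TraceSet:
    """Per-ROI traces at line rate, with the ordered list of processing steps."""

    traces: dict[int, Trace]
    provenance: list[str] = field(default_factory=list)

    @property
    def roi_ids(self) -> list[int]:
        return sorted(self.traces)

    def __len__(self) -> int:
        return len(self.traces)


# ---------------------------------------------------------------------------
# Pixel classification
# ---------------------------------------------------------------------------

def classify_pixels(traj: SLSTrajectory, ref_seg: Segmentation) -> PixelClassification:
    """Classify trajectory pixels by distance to the reference segmentation.

    For each pixel, the distance to a ROI is the minimum Euclidean distance to
    any of that ROI's pixels.  Bands: [0, 1] ROI, (1, 2] outer ring, (2, 4]
    surround.  A pixel falling in a band of exactly one ROI takes that class;
    in bands of two or more ROIs it is discarded; farther than 4 px from every
    ROI it is background.
    """
    if ref_seg.n_rois == 0:
        raise DataError("empty reference segmentation")
    coords = traj.coords.astype(float)
    n = coords.shape[0]
    ids = [roi.id for roi in ref_seg.rois]
    dmat = np.empty((n, len(ids)))
    for j, roi in enumerate(ref_seg.rois):
        dmat[:, j] = cdist(coords, roi.pixels.astype(float)).min(axis=1)
    in_band = dmat <= SURROUND_BAND
    n_claims = in_band.sum(axis=1)
    category: list[str] = []
    roi_id: list[Optional[int]] = []
    distance = np.full(n, np.nan)
    for i in range(n):
        if n_claims[i] == 0:
            category.append("background")
            roi_id.append(None)
            distance[i] = dmat[i].min()
        elif n_claims[i] > 1:
            category.append("discarded")
            roi_id.append(None)
            distance[i] = dmat[i].min()
        else:
            j = int(np.argmax(in_band[i]))
            d = dmat[i, j]
            if d <= ROI_BAND:
                category.append("roi")
            elif d <= OUTER_RING_BAND:
                category.append("outer_ring")
            else:
                category.append("surround")
            roi_id.append(ids[j])
            distance[i] = d
    return PixelClassification(category=category, roi_id=roi_id, distance=distance)


# ---------------------------------------------------------------------------
# Large-artefact detection
# ---------------------------------------------------------------------------

def _pc1_scores(data: np.ndarray) -> np.ndarray:
    """Scores of the first principal component across pixels (per-pixel
    centering; component sign fixed so the mean loading is non-negative)."""
    centered = data - data.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    v1 = vt[0]
    if v1.mean() < 0:
        v1 = -v1
    return centered @ v1


def _window_lines(window_s: float, line_period: float) -> int:
    return max(2, int(round(window_s / line_period)))


def detect_large_artifact(rec: SLSRecording, window_s: float = 10.0,
                          threshold: float = 0.3) -> ArtifactReport:
    """Detect a large motion artefact from the recording's PC1 dynamics.

    The PC1 score series is fitted with an AR(2) model (OLS of s_t on its two
    lags, no intercept: PC1 scores are zero-mean); the Pearson correlation
    between scores and one-step predictions is evaluated in a trailing window
    of ``round(window_s / line_period)`` lines.  The first line whose window
    correlation drops below ``threshold`` becomes ``crop_index``; all later
    lines are flagged for discard.
    """
    W = _window_lines(window_s, rec.trajectory.line_period)
    n = rec.n_lines
    if n <= 3 * W:
        raise DataError(f"recording of {n} lines too short for a {W}-line window")
    s = _pc1_scores(rec.lines)
    # AR(2) by OLS on lagged scores
    X = np.column_stack([s[1:-1], s[:-2]])
    y = s[2:]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    fit = np.empty_like(s)
    fit[0] = s[0]                     # free predictions for the first two lines
    fit[1] = coef[0] * s[0]
    fit[2:] = X @ coef

    corr = np.full(n, np.nan)
    for t in range(W - 1, n):
        a = s[t - W + 1: t + 1]
        b = fit[t - W + 1: t + 1]
        sa, sb = a.std(), b.std()
        corr[t] = ((a - a.mean()) @ (b - b.mean())) / (W * sa * sb) if sa > 0 and sb > 0 else 0.0
    crossing = np.flatnonzero(corr[W - 1:] < threshold)
    crop = int(crossing[0] + W - 1) if crossing.size else None
    return ArtifactReport(pc1_scores=s, ar2_fit=fit, sliding_corr=corr,
                          crop_index=crop, threshold=threshold, window_s=window_s)


# ---------------------------------------------------------------------------
# Background subtraction
# ---------------------------------------------------------------------------

def _rank1_reconstruction(data: np.ndarray) -> np.ndarray:
    """Rank-1 PCA reconstruction of [n_samples, n_series] data: per-series
    centering, leading component only, means re-added."""
    means = data.mean(axis=0)
    centered = data - means
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    v1 = vt[0]
    if v1.mean() < 0:
        v1 = -v1
    scores = centered @ v1
    return np.outer(scores, v1) + means


def subtract_background(rec: SLSRecording, cls: PixelClassification,
                        ratio: float = 0.7) -> SLSRecording:
    """Remove the shared background from every trajectory pixel.

    Background-pixel activity is reduced to its rank-1 PCA reconstruction,
    averaged across background pixels into a single series b(t), scaled by
    ``ratio`` and subtracted from all pixels; negatives are clipped to zero.
    """
    bg = cls.indices("background")
    if bg.size < 2:
        raise DataError("background subtraction needs at least 2 background "
                        "pixels; scan background pixels or skip this step")
    recon = _rank1_reconstruction(rec.lines[:, bg])
    b = recon.mean(axis=1)
    lines = np.maximum(0.0, rec.lines - ratio * b[:, None])
    return SLSRecording(lines=lines, timestamps=rec.timestamps,
                        trajectory=rec.trajectory, crop_index=rec.crop_index)


# ---------------------------------------------------------------------------
# Windowed SNR (vectorised helper)
# ---------------------------------------------------------------------------

def _forward_window_snr(data: np.ndarray, window: int, chunk: int = 64) -> np.ndarray:
    """SNR of each pixel over the forward window [t, t+window), truncated at
    the end of the recording.  ``data`` is [n_lines, n_pixels]; returns
    [n_lines, n_pixels] with -inf where the statistic is degenerate.
    """
    n, m = data.shape
    out = np.empty((n, m))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        for t in range(start, stop):
            win = data[t: min(t + window, n)]            # [w, m]
            p25 = np.percentile(win, 25, axis=0)
            mask = win < p25
            cnt = mask.sum(axis=0)
            safe = np.maximum(cnt, 1)
            mean = (win * mask).sum(axis=0) / safe
            var = (win ** 2 * mask).sum(axis=0) / safe - mean ** 2
            var = np.maximum(var, 0.0)
            sd = np.sqrt(var)
            ok = (cnt > 0) & (sd > 0)
            with np.errstate(divide="ignore", invalid="ignore"):
                s = (win.max(axis=0) - mean) / sd
            out[t] = np.where(ok, s, -np.inf)
    return out


# ---------------------------------------------------------------------------
# Motion correction
# ---------------------------------------------------------------------------

def correct_motion_snr(rec: SLSRecording, cls: PixelClassification,
                       ref_seg: Segmentation, window_s: float = 10.0
                       ) -> LineAssignment:
    """Line-by-line pixel reassignment by forward-window SNR ranking.

    For each ROI, the candidate pool is its ROI + outer-ring + surround pixels.
    At every line t the SNR of each pool pixel over the next ``window_s``
    seconds is computed, pixels are sorted by descending SNR (ties broken by
    (row, col) ascending) and the top n_ref pixels — n_ref being the number of
    trajectory pixels labelled as belonging to the ROI, its operational
    footprint — become the ROI's pixels for that line.
    """
    W = _window_lines(window_s, rec.trajectory.line_period)
    n = rec.n_lines
    assigned: dict[int, np.ndarray] = {}
    pools: dict[int, np.ndarray] = {}
    coords = rec.trajectory.coords
    for roi in ref_seg.rois:
        pool = cls.pool_indices(roi.id)
        n_ref = cls.indices("roi", roi.id).size
        if n_ref == 0:
            raise DataError(f"ROI {roi.id} has no trajectory pixels labelled as ROI")
        if pool.size < n_ref:
            raise DataError(f"ROI {roi.id}: candidate pool of {pool.size} pixels is "
                            f"smaller than the reference count {n_ref}")
        snrs = _forward_window_snr(rec.lines[:, pool], W)   # [n, n_pool]
        rows = coords[pool, 0]
        cols = coords[pool, 1]
        sel = np.empty((n, n_ref), dtype=int)
        for t in range(n):
            order = np.lexsort((cols, rows, -snrs[t]))
            sel[t] = pool[order[:n_ref]]
        assigned[roi.id] = sel
        pools[roi.id] = pool
    return LineAssignment(assigned=assigned, pool=pools, n_lines=n)


def correct_motion_refbox(rec: SLSRecording, ref_seg: Segmentation,
                          cls: Optional[PixelClassification] = None,
                          smooth_window_s: float = 0.0,
                          downsample: bool = False,
                          n_template: int = 10,
                          max_shift: Optional[int] = None
                          ) -> tuple[np.ndarray, LineAssignment]:
    """Line-by-line motion correction from the reference-box image sequence.

    The refbox pixels of every line are reshaped into a small image; the image
    sequence (optionally smoothed by a sliding mean of ``smooth_window_s``
    seconds, and optionally decimated to window centers) is rigidly registered
    to its first-frames template.  The per-line planar displacement (dy, dx) is
    the negated registration correction, interpolated back to all lines by
    nearest assignment.  Each ROI's operational footprint (its class-ROI
    trajectory pixels), shifted by the rounded displacement, is mapped onto
    the ROI's candidate pool; shifted pixels not on the trajectory are dropped
    from that line's assignment.

    Returns (displacements [n_lines, 2], LineAssignment).
    """
    traj = rec.trajectory
    if traj.refbox is None:
        raise DataError("trajectory has no reference box")
    r0, c0, h, w = traj.refbox
    if h < 4 or w < 4:
        raise DataError("reference box must be at least 4x4 pixels")
    if cls is None:
        cls = classify_pixels(traj, ref_seg)
    n = rec.n_lines
    box = rec.lines[:, traj.refbox_pixel_indices()].reshape(n, h, w)

    S = _window_lines(smooth_window_s, traj.line_period) if smooth_window_s > 0 else 1
    if S > 1:
        kernel = np.ones(S) / S
        sm = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="valid"),
                                 0, box.reshape(n, h * w)).reshape(-1, h, w)
        centers = np.arange(sm.shape[0]) + (S - 1) / 2
        if downsample:
            sm = sm[::S]
            centers = centers[::S]
    else:
        sm = box
        centers = np.arange(n, dtype=float)

    meta = AcquisitionMetadata(pixel_size=1.0, frame_period=traj.line_period,
                               line_period=traj.line_period, dwell_time=1.0)
    if max_shift is None:
        max_shift = max(1, min(h, w) // 2 - 1)
    reg = rp.register_raster(RasterMovie(sm, meta), mode="rigid",
                             n_template=min(n_template, sm.shape[0]),
                             max_shift=max_shift)
    disp_sm = -reg.shifts                                   # tissue displacement
    # nearest-line interpolation back to all lines
    idx = np.abs(centers[None, :] - np.arange(n)[:, None]).argmin(axis=1)
    disp = disp_sm[idx]

    coord_to_idx = {tuple(p): i for i, p in enumerate(traj.coords)}
    assigned: dict[int, np.ndarray] = {}
    pools: dict[int, np.ndarray] = {}
    rounded = np.rint(disp).astype(int)
    uniq, inverse = np.unique(rounded, axis=0, return_inverse=True)
    for roi in ref_seg.rois:
        pool = cls.pool_indices(roi.id)
        pool_set = set(pool.tolist())
        footprint = traj.coords[cls.indices("roi", roi.id)]
        per_shift: list[np.ndarray] = []
        for dy, dx in uniq:
            hit = []
            for r, c in footprint:
                j = coord_to_idx.get((int(r) + int(dy), int(c) + int(dx)))
                if j is not None and j in pool_set:
                    hit.append(j)
            per_shift.append(np.array(sorted(hit), dtype=int))
        sel = [per_shift[inverse[t]] for t in range(n)]
        assigned[roi.id] = _ragged(sel)
        pools[roi.id] = pool
    return disp, LineAssignment(assigned=assigned, pool=pools, n_lines=n)


def _ragged(rows: list[np.ndarray]) -> np.ndarray:
    """Store per-line index sets of varying size as an object array unless they
    are rectangular."""
    sizes = {r.size for r in rows}
    if len(sizes) == 1:
        return np.stack(rows)
    out = np.empty(len(rows), dtype=object)
    for i, r in enumerate(rows):
        out[i] = r
    return out


def _line_sets(assignment_entry: np.ndarray, n_lines: int) -> list[np.ndarray]:
    if assignment_entry.dtype == object:
        return [assignment_entry[t] for t in range(n_lines)]
    return [assignment_entry[t] for t in range(n_lines)]


# ---------------------------------------------------------------------------
# Trace extraction and neuropil decontamination
# ---------------------------------------------------------------------------

def extract_traces(rec: SLSRecording,
                   assignment: LineAssignment | PixelClassification) -> TraceSet:
    """Per-ROI traces: at each line, the mean of the pixels assigned to the ROI."""
    if isinstance(assignment, PixelClassification):
        assignment = LineAssignment.static(assignment, rec.n_lines)
    rate = rec.line_rate
    traces: dict[int, Trace] = {}
    for k, sel in assignment.assigned.items():
        vals = np.empty(rec.n_lines)
        for t, idx in enumerate(_line_sets(sel, rec.n_lines)):
            if idx.size == 0:
                raise DataError(f"ROI {k}: empty pixel assignment at line {t}")
            vals[t] = rec.lines[t, idx].mean()
        traces[k] = Trace(vals, rate)
    return TraceSet(traces=traces, provenance=["extract_traces"])


def subtract_neuropil_local(rec: SLSRecording,
                            cls: PixelClassification,
                            assignment: Optional[LineAssignment] = None,
                            ratio: float = 0.7) -> TraceSet:
    """Local neuropil decontamination.

    Per ROI and line: trace = mean over assigned ROI pixels - ``ratio`` x mean
    over the neuropil pixels (the surround-class pixels, or — after line-by-line
    reassignment — the per-line unassigned pool pixels), clipped at zero.  A
    ROI with no neuropil pixels passes through unchanged and is flagged in the
    provenance.
    """
    n = rec.n_lines
    if assignment is None:
        assignment = LineAssignment.static(cls, n)
    rate = rec.line_rate
    traces: dict[int, Trace] = {}
    provenance = ["subtract_neuropil_local"]
    for k, sel in assignment.assigned.items():
        roi_vals = np.empty(n)
        np_vals = np.zeros(n)
        has_np = True
        static_np = cls.indices("surround", k)
        for t, idx in enumerate(_line_sets(sel, n)):
            if idx.size == 0:
                raise DataError(f"ROI {k}: empty pixel assignment at line {t}")
            roi_vals[t] = rec.lines[t, idx].mean()
            pool = assignment.pool[k]
            un = np.setdiff1d(pool, idx, assume_unique=False)
            npix = un if un.size else static_np
            if npix.size == 0:
                has_np = False
                break
            np_vals[t] = rec.lines[t, npix].mean()
        if not has_np:
            for t, idx in enumerate(_line_sets(sel, n)):
                roi_vals[t] = rec.lines[t, idx].mean()
            traces[k] = Trace(roi_vals, rate)
            provenance.append(f"roi {k}: no neuropil pixels, passed through")
        else:
            traces[k] = Trace(np.maximum(0.0, roi_vals - ratio * np_vals), rate)
    return TraceSet(traces=traces, provenance=provenance)


def subtract_neuropil_global(rec: SLSRecording,
                             cls: PixelClassification,
                             assignment: Optional[LineAssignment] = None) -> TraceSet:
    """Global neuropil decontamination by rank-1 PCA across ROI signals.

    Per ROI, a signal is the mean over its assigned ROI pixels plus its
    surround pixels; the rank-1 PCA reconstruction of these signals is taken as
    the global neuropil and subtracted from each ROI's plain ROI-pixel trace
    (negatives clipped).
    """
    n = rec.n_lines
    if assignment is None:
        assignment = LineAssignment.static(cls, n)
    ids = sorted(assignment.assigned)
    if len(ids) < 2:
        raise DataError("global neuropil subtraction needs at least 2 ROIs")
    rate = rec.line_rate
    signals = np.empty((n, len(ids)))
    plain = np.empty((n, len(ids)))
    for j, k in enumerate(ids):
        surround = cls.indices("surround", k)
        for t, idx in enumerate(_line_sets(assignment.assigned[k], n)):
            if idx.size == 0:
                raise DataError(f"ROI {k}: empty pixel assignment at line {t}")
            plain[t, j] = rec.lines[t, idx].mean()
            both = np.union1d(idx, surround) if surround.size else idx
            signals[t, j] = rec.lines[t, both].mean()
    recon = _rank1_reconstruction(signals)
    out = np.maximum(0.0, plain - recon)
    traces = {k: Trace(out[:, j], rate) for j, k in enumerate(ids)}
    return TraceSet(traces=traces, provenance=["subtract_neuropil_global"])


# ---------------------------------------------------------------------------
# Deconvolution and quality metrics
# ---------------------------------------------------------------------------

def deconvolve_sls(traces: TraceSet) -> TraceSet:
    """Normalise each ROI trace (dF/F0) and deconvolve it with the AR kernel
    selected by the acquisition-rate rule (AR(2) at line rates >= 2 Hz)."""
    activities: dict[int, Trace] = {}
    for k, tr in traces.traces.items():
        norm = rp.dff(tr)
        _, activity, _ = rp.deconvolve(norm)
        activities[k] = activity
    return TraceSet(traces=activities,
                    provenance=traces.provenance + ["deconvolve_sls"])


def mean_pairwise_correlation(traces: TraceSet) -> Optional[float]:
    ids = traces.roi_ids
    if len(ids) < 2:
        return None
    vals = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a = traces.traces[ids[i]].values
            b = traces.traces[ids[j]].values
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                vals.append(0.0)
            else:
                vals.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(vals))


def mean_snr(traces: TraceSet) -> Optional[float]:
    """Mean per-ROI SNR; degenerate traces (e.g. heavily clipped, with an empty
    sub-25th-percentile sample) are excluded; None when every trace is degenerate."""
    vals = []
    for tr in traces.traces.values():
        s = rp.snr_or_none(tr)
        if s is not None:
            vals.append(s)
    return float(np.mean(vals)) if vals else None


def quality_metrics(before: TraceSet, after: TraceSet) -> dict:
    """Pipeline validation metrics: change in mean per-ROI SNR and in mean
    pairwise Pearson correlation (after - before).  With fewer than two ROIs
    the correlation delta is reported as None."""
    if before.roi_ids != after.roi_ids:
        raise DataError("trace sets cover different ROI sets")
    for k in before.roi_ids:
        if len(before.traces[k]) != len(after.traces[k]):
            raise DataError("trace sets have different lengths")
    sb, sa = mean_snr(before), mean_snr(after)
    d_snr = None if sb is None or sa is None else float(sa - sb)
    cb = mean_pairwise_correlation(before)
    ca = mean_pairwise_correlation(after)
    d_corr = None if cb is None else float(ca - cb)
    return {"delta_snr": d_snr, "delta_corr": d_corr,
            "snr_before": sb, "snr_after": sa,
            "corr_before": cb, "corr_after": ca}


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

MOTION_STEPS = {"correct_motion_snr", "correct_motion_refbox"}
NEUROPIL_STEPS = {"subtract_neuropil_local", "subtract_neuropil_global"}
KNOWN_STEPS = {"crop_large_artifacts", "subtract_background"} | MOTION_STEPS | NEUROPIL_STEPS


def run_pipeline(rec: SLSRecording, ref_seg: Segmentation,
                 steps: Sequence[str], params: Optional[dict] = None
                 ) -> tuple[TraceSet, Optional[ArtifactReport], dict]:
    """Apply an ordered list of processing steps to an SLS recording.

    ``steps`` may contain ``crop_large_artifacts``, ``subtract_background``,
    one of the two motion corrections and one of the two neuropil
    decontaminations, in any order.  Pixel classification against ``ref_seg``
    is computed first.  Metrics compare the final traces with the raw traces
    (static classification on the raw recording).

    Returns (traces, artifact report or None, metrics dict).
    """
    params = dict(params or {})
    steps = list(steps)
    unknown = [s for s in steps if s not in KNOWN_STEPS]
    if unknown:
        raise ConfigError(f"unknown step(s): {', '.join(unknown)}")
    if len(MOTION_STEPS & set(steps)) > 1:
        raise ConfigError("choose at most one motion-correction step")
    if len(NEUROPIL_STEPS & set(steps)) > 1:
        raise ConfigError("choose at most one neuropil-decontamination step")
    # pre-flight feature checks
    cls = classify_pixels(rec.trajectory, ref_seg)
    if "correct_motion_refbox" in steps and rec.trajectory.refbox is None:
        raise ConfigError("correct_motion_refbox requires a trajectory with a reference box")
    if "subtract_background" in steps and cls.indices("background").size < 2:
        raise ConfigError("subtract_background requires at least 2 background pixels")

    raw_traces = extract_traces(rec, cls)
    report: Optional[ArtifactReport] = None
    assignment: Optional[LineAssignment] = None
    traces: Optional[TraceSet] = None
    provenance: list[str] = []
    current = rec

    for step in steps:
        if step == "crop_large_artifacts":
            report = detect_large_artifact(
                current,
                window_s=params.get("window_s", 10.0),
                threshold=params.get("threshold", 0.3))
            if report.crop_index is not None:
                current = SLSRecording(current.lines[: report.crop_index],
                                       current.timestamps[: report.crop_index],
                                       current.trajectory)
                assignment = None   # line count changed
        elif step == "subtract_background":
            current = subtract_background(current, cls,
                                          ratio=params.get("ratio", 0.7))
        elif step == "correct_motion_snr":
            assignment = correct_motion_snr(current, cls, ref_seg,
                                            window_s=params.get("window_s", 10.0))
        elif step == "correct_motion_refbox":
            _, assignment = correct_motion_refbox(
                current, ref_seg, cls,
                smooth_window_s=params.get("smooth_window_s", 0.0),
                downsample=params.get("downsample", False))
        elif step == "subtract_neuropil_local":
            traces = subtract_neuropil_local(current, cls, assignment,
                                             ratio=params.get("ratio", 0.7))
        elif step == "subtract_neuropil_global":
            traces = subtract_neuropil_global(current, cls, assignment)
        provenance.append(step)

    if traces is None:
        traces = extract_traces(current, assignment if assignment is not None else cls)
    traces = TraceSet(traces=traces.traces, provenance=provenance or ["raw"])

    # metrics against raw traces (truncated to the processed length if cropped)
    n = len(next(iter(traces.traces.values())))
    raw_cut = TraceSet(traces={k: Trace(tr.values[:n], tr.rate)
                               for k, tr in raw_traces.traces.items()},
                       provenance=["raw"])
    metrics = quality_metrics(raw_cut, traces)
    return traces, report, metrics
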
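"""Domain types and readers/writers for movies, segmentations, trajectories and
smart-line-scan (SLS) recordings.

Coordinate convention: 0-based ``(row, col)``, row-major, origin at the top-left
pixel of the field of view (FOV).  Segmentation matrices are vectorised row-major
by default; a flag accepts column-major matrices produced by Matlab-heritage
tools.  Acquisition metadata travels as a sidecar JSON file next to the pixel
data; SLS recordings use an HDF5 container with ``lines`` and ``timestamps``
datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import h5py
import numpy as np
import pandas as pd
import tifffile

from .errors import DataError

__all__ = [
    "AcquisitionMetadata",
    "RasterMovie",
    "ROI",
    "Segmentation",
    "SLSTrajectory",
    "SLSRecording",
    "load_raster_movie",
    "save_raster_movie",
    "load_segmentation_matrix",
    "save_segmentation_matrix",
    "load_segmentation_mask",
    "save_segmentation_mask",
    "load_trajectory",
    "save_trajectory",
    "load_sls_recording",
    "save_sls_recording",
    "sls_to_raster",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionMetadata:
    """Acquisition timing and geometry.

    Parameters
    ----------
    pixel_size : float
        Lateral pixel size, micrometres per pixel.
    frame_period : float
        Time between consecutive raster frames, seconds.
    line_period : float
        Time to scan one full line (one SLS trajectory pass), seconds.
    dwell_time : float
        Per-pixel dwell time, microseconds.
    """

    pixel_size: float
    frame_period: float
    line_period: float
    dwell_time: float

    def __post_init__(self) -> None:
        for name in ("pixel_size", "frame_period", "line_period", "dwell_time"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise DataError(f"metadata field {name!r} must be strictly positive, got {v}")

    def to_dict(self) -> dict:
        return {
            "pixel_size": self.pixel_size,
            "frame_period": self.frame_period,
            "line_period": self.line_period,
            "dwell_time": self.dwell_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionMetadata":
        missing = [k for k in ("pixel_size", "frame_period", "line_period", "dwell_time")
                   if k not in d]
        if missing:
            raise DataError(f"metadata missing required field(s): {', '.join(missing)}")
        return cls(**{k: float(d[k]) for k in
                      ("pixel_size", "frame_period", "line_period", "dwell_time")})


@dataclass
class RasterMovie:
    """A time-ordered stack of 2D frames with acquisition metadata.

    ``frames`` has shape ``[T, H, W]``, non-negative fluorescence counts.
    """

    frames: np.ndarray
    meta: AcquisitionMetadata

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise DataError(f"frames must be [T, H, W], got shape {self.frames.shape}")
        if min(self.frames.shape) < 1:
            raise DataError("empty movie")
        if not np.all(np.isfinite(self.frames)):
            raise DataError("movie contains NaN or Inf values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def fov_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class ROI:
    """A weighted pixel footprint of one region of interest (a soma).

    ``pixels`` is an ``[n, 2]`` integer array of (row, col) coordinates and
    ``weights`` the matching non-negative per-pixel weights.  The centroid is
    the weight-mean of the pixel coordinates.
    """

    id: int
    pixels: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.atleast_2d(np.asarray(self.pixels, dtype=int))
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if self.pixels.shape[0] == 0:
            raise DataError(f"ROI {self.id} has no pixels")
        if self.pixels.shape != (self.weights.shape[0], 2):
            raise DataError(f"ROI {self.id}: pixels/weights shape mismatch")
        if not np.all(np.isfinite(self.weights)):
            raise DataError(f"ROI {self.id}: non-finite weight")
        if np.any(self.weights < 0):
            raise DataError(f"ROI {self.id}: negative weight")
        if self.weights.sum() <= 0:
            raise DataError(f"ROI {self.id}: weights sum to zero")

    @property
    def centroid(self) -> tuple[float, float]:
        w = self.weights / self.weights.sum()
        r, c = (self.pixels * w[:, None]).sum(axis=0)
        return float(r), float(c)

    @property
    def n_pixels(self) -> int:
        return self.pixels.shape[0]

    def pixel_set(self) -> set[tuple[int, int]]:
        return {(int(r), int(c)) for r, c in self.pixels}


@dataclass
class Segmentation:
    """An ordered list of ROIs on a FOV grid, with optional surround footprints.

    ``surrounds`` maps ROI id to an ``[m, 2]`` array of surround pixel
    coordinates; it is empty when ``surround_width`` is 0.
    """

    fov_shape: tuple[int, int]
    rois: list[ROI]
    surround_width: int = 0
    surrounds: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        H, W = self.fov_shape
        ids = [r.id for r in self.rois]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate ROI ids in segmentation")
        for roi in self.rois:
            if (roi.pixels[:, 0].min() < 0 or roi.pixels[:, 1].min() < 0
                    or roi.pixels[:, 0].max() >= H or roi.pixels[:, 1].max() >= W):
                raise DataError(f"ROI {roi.id} has pixels outside the {H}x{W} FOV")
        if self.surround_width == 0 and self.surrounds:
            raise DataError("surround footprints present but surround_width is 0")

    @property
    def n_rois(self) -> int:
        return len(self.rois)

    def roi_by_id(self, roi_id: int) -> ROI:
        for roi in self.rois:
            if roi.id == roi_id:
                return roi
        raise KeyError(f"no ROI with id {roi_id}")

    def label_mask(self) -> np.ndarray:
        """Render as an integer label image (0 = background, ids elsewhere).
        Overlapping pixels take the id of the later ROI in the list."""
        mask = np.zeros(self.fov_shape, dtype=np.uint16)
        for roi in self.rois:
            mask[roi.pixels[:, 0], roi.pixels[:, 1]] = roi.id
        return mask


#: per-pixel provenance labels on a trajectory
ROI_LABEL = "roi"
SURROUND_LABEL = "surround"
REFBOX_LABEL = "refbox"


@dataclass
class SLSTrajectory:
    """An ordered scan path through the FOV.

    ``coords`` is ``[n, 2]`` integer (row, col); ``labels`` carries per-pixel
    provenance as ``("roi", k)``, ``("surround", k)`` or ``("refbox", None)``.
    ``refbox`` is an optional ``(row0, col0, height, width)`` rectangle whose
    pixels sit contiguously at the end of ``coords`` in row-major order.
    """

    coords: np.ndarray
    labels: list[tuple[str, Optional[int]]]
    line_period: float
    refbox: Optional[tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=int))
        if self.coords.shape[0] != len(self.labels):
            raise DataError("trajectory coords/labels length mismatch")
        if self.line_period <= 0:
            raise DataError("line_period must be positive")
        if self.refbox is not None:
            r0, c0, h, w = self.refbox
            if h < 1 or w < 1:
                raise DataError("refbox must have positive size")
            expect = [(r0 + i, c0 + j) for i in range(h) for j in range(w)]
            tail = [tuple(p) for p in self.coords[-h * w:]]
            if tail != expect:
                raise DataError("refbox pixels must be contiguous at the end of the "
                                "trajectory in row-major order")

    @property
    def n_pixels(self) -> int:
        return self.coords.shape[0]

    @property
    def line_rate(self) -> float:
        return 1.0 / self.line_period

    def refbox_pixel_indices(self) -> np.ndarray:
        if self.refbox is None:
            raise DataError("trajectory has no reference box")
        r0, c0, h, w = self.refbox
        return np.arange(self.n_pixels - h * w, self.n_pixels)


@dataclass
class SLSRecording:
    """Fluorescence recorded along an SLS trajectory.

    ``lines`` is ``[n_lines, n_pixels]`` with one row per trajectory pass and
    one column per trajectory pixel; ``timestamps`` are the per-line times in
    seconds, strictly increasing with spacing equal to the trajectory's line
    period.
    """

    lines: np.ndarray
    timestamps: np.ndarray
    trajectory: SLSTrajectory
    crop_index: Optional[int] = None

    def __post_init__(self) -> None:
        self.lines = np.atleast_2d(np.asarray(self.lines, dtype=float))
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if not np.all(np.isfinite(self.lines)):
            raise DataError("recording contains NaN or Inf values")
        if self.lines.shape[1] != self.trajectory.n_pixels:
            raise DataError(
                f"recording has {self.lines.shape[1]} pixels per line but the "
                f"trajectory has {self.trajectory.n_pixels}")
        if self.timestamps.shape != (self.lines.shape[0],):
            raise DataError("timestamps length must equal number of lines")
        dt = np.diff(self.timestamps)
        if self.lines.shape[0] > 1:
            if np.any(dt <= 0):
                raise DataError("timestamps must be strictly increasing")
            if not np.allclose(dt, self.trajectory.line_period, rtol=1e-6, atol=1e-9):
                raise DataError("timestamp spacing must equal the line period")

    @property
    def n_lines(self) -> int:
        return self.lines.shape[0]

    @property
    def line_rate(self) -> float:
        return self.trajectory.line_rate

    def cropped(self) -> "SLSRecording":
        """Return the recording truncated at ``crop_index`` (identity if unset)."""
        if self.crop_index is None:
            return self
        return SLSRecording(self.lines[: self.crop_index],
                            self.timestamps[: self.crop_index],
                            self.trajectory)


# ---------------------------------------------------------------------------
# Movies
# ---------------------------------------------------------------------------

def load_raster_movie(path, meta: AcquisitionMetadata) -> RasterMovie:
    """Load a raster movie from a multi-page TIFF or a sequence of TIFF files.

    A sequence of paths is read in lexicographic filename order, one or more
    frames per file.  Values are taken as stored, without rescaling.
    """
    if isinstance(path, (str, Path)):
        paths = [Path(path)]
    else:
        paths = sorted((Path(p) for p in path), key=lambda p: p.name)
    if not paths:
        raise DataError("no input files given")
    stacks = []
    shape = None
    for p in paths:
        try:
            arr = tifffile.imread(p)
        except Exception as exc:  # pragma: no cover - passthrough detail
            raise DataError(f"unreadable TIFF file {p}: {exc}") from exc
        arr = np.asarray(arr)
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim != 3:
            raise DataError(f"{p}: expected 2D pages, got array of ndim {arr.ndim}")
        if shape is None:
            shape = arr.shape[1:]
        elif arr.shape[1:] != shape:
            raise DataError(f"{p}: page shape {arr.shape[1:]} differs from {shape}")
        stacks.append(arr)
    frames = np.concatenate(stacks, axis=0)
    return RasterMovie(frames=frames, meta=meta)


def save_raster_movie(movie: RasterMovie, path, sidecar: bool = True) -> None:
    """Write a movie as a multi-page float32 TIFF plus a metadata sidecar JSON."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames.astype(np.float32))
    if sidecar:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(movie.meta.to_dict(), indent=1))


def load_movie_metadata(path) -> AcquisitionMetadata:
    """Read an AcquisitionMetadata sidecar JSON."""
    return AcquisitionMetadata.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Segmentations
# ---------------------------------------------------------------------------

def load_segmentation_matrix(path, fov_shape: tuple[int, int],
                             order: str = "C") -> Segmentation:
    """Load a pixel-by-ROI weight matrix (CSV/TXT) as a Segmentation.

    The matrix has ``H*W`` rows (FOV pixels, vectorised with ``order``:
    ``"C"`` row-major or ``"F"`` column-major) and one column per ROI; each
    column holds non-negative weights on that ROI's pixels.
    """
    H, W = fov_shape
    try:
        mat = pd.read_csv(path, header=None).to_numpy(dtype=float)
    except Exception:
        try:
            mat = pd.read_csv(path, header=None, sep=r"\s+").to_numpy(dtype=float)
        except Exception as exc:
            raise DataError(f"unreadable segmentation matrix {path}: {exc}") from exc
    return segmentation_from_matrix(mat, fov_shape, order=order)


def segmentation_from_matrix(mat: np.ndarray, fov_shape: tuple[int, int],
                             order: str = "C") -> Segmentation:
    """Build a Segmentation from an in-memory [H*W, n_rois] weight matrix."""
    H, W = fov_shape
    mat = np.atleast_2d(np.asarray(mat, dtype=float))
    if not np.all(np.isfinite(mat)):
        raise DataError("segmentation matrix contains NaN or Inf")
    if mat.shape[0] != H * W:
        raise DataError(f"segmentation matrix has {mat.shape[0]} rows, "
                        f"expected H*W = {H * W}")
    if np.any(mat < 0):
        raise DataError("negative weight in segmentation matrix")
    if order not in ("C", "F"):
        raise DataError("order must be 'C' (row-major) or 'F' (column-major)")
    rois = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        idx = np.flatnonzero(col > 0)
        if idx.size == 0:
            raise DataError(f"segmentation column {j} is all-zero")
        if order == "C":
            rows, cols = np.divmod(idx, W)
        else:
            cols, rows = np.divmod(idx, H)
        rois.append(ROI(id=j + 1, pixels=np.column_stack([rows, cols]),
                        weights=col[idx]))
    return Segmentation(fov_shape=fov_shape, rois=rois)


def save_segmentation_matrix(seg: Segmentation, path, order: str = "C") -> None:
    """Write a Segmentation as an [H*W, n_rois] CSV weight matrix."""
    H, W = seg.fov_shape
    mat = np.zeros((H * W, seg.n_rois))
    for j, roi in enumerate(seg.rois):
        if order == "C":
            flat = roi.pixels[:, 0] * W + roi.pixels[:, 1]
        else:
            flat = roi.pixels[:, 1] * H + roi.pixels[:, 0]
        mat[flat, j] = roi.weights
    pd.DataFrame(mat).to_csv(path, header=False, index=False)


def load_segmentation_mask(path) -> Segmentation:
    """Load a 16-bit integer label-mask TIFF (0 = background) as a Segmentation."""
    mask = np.asarray(tifffile.imread(path))
    if mask.ndim != 2:
        raise DataError("label mask must be a single 2D image")
    if not np.all(np.isfinite(mask)):
        raise DataError("label mask contains NaN or Inf")
    rois = []
    for lab in np.unique(mask):
        if lab == 0:
            continue
        rr, cc = np.nonzero(mask == lab)
        rois.append(ROI(id=int(lab), pixels=np.column_stack([rr, cc]),
                        weights=np.ones(rr.size)))
    return Segmentation(fov_shape=mask.shape, rois=rois)


def save_segmentation_mask(seg: Segmentation, path) -> None:
    tifffile.imwrite(Path(path), seg.label_mask())


# ---------------------------------------------------------------------------
# Trajectories (JSON schema: list of [row, col, label] plus refbox, line_period)
# ---------------------------------------------------------------------------

def _label_to_str(label: tuple[str, Optional[int]]) -> str:
    kind, k = label
    return kind if k is None else f"{kind}:{k}"


def _label_from_str(s: str) -> tuple[str, Optional[int]]:
    if ":" in s:
        kind, k = s.split(":", 1)
        return kind, int(k)
    return s, None


def save_trajectory(traj: SLSTrajectory, path) -> None:
    doc = {
        "schema": "smartline-trajectory-v1",
        "coords": [[int(r), int(c), _label_to_str(lab)]
                   for (r, c), lab in zip(traj.coords, traj.labels)],
        "refbox": list(traj.refbox) if traj.refbox is not None else None,
        "line_period": traj.line_period,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_trajectory(path) -> SLSTrajectory:
    doc = json.loads(Path(path).read_text())
    coords = np.array([[r, c] for r, c, _ in doc["coords"]], dtype=int)
    labels = [_label_from_str(lab) for _, _, lab in doc["coords"]]
    refbox = tuple(doc["refbox"]) if doc.get("refbox") else None
    return SLSTrajectory(coords=coords, labels=labels,
                         line_period=float(doc["line_period"]), refbox=refbox)


def trajectory_to_csv(traj: SLSTrajectory, path) -> None:
    df = pd.DataFrame({
        "index": np.arange(traj.n_pixels),
        "row": traj.coords[:, 0],
        "col": traj.coords[:, 1],
        "label": [_label_to_str(lab) for lab in traj.labels],
    })
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# SLS recordings (HDF5 container)
# ---------------------------------------------------------------------------

def save_sls_recording(rec: SLSRecording, path) -> None:
    """Write an SLS recording to HDF5: datasets ``lines`` and ``timestamps``,
    the trajectory serialised as a JSON attribute."""
    with h5py.File(path, "w") as f:
        # track_times=False keeps files byte-identical across reruns
        f.create_dataset("lines", data=rec.lines, track_times=False)
        f.create_dataset("timestamps", data=rec.timestamps, track_times=False)
        doc = {
            "coords": [[int(r), int(c), _label_to_str(lab)]
                       for (r, c), lab in zip(rec.trajectory.coords, rec.trajectory.labels)],
            "refbox": list(rec.trajectory.refbox) if rec.trajectory.refbox else None,
            "line_period": rec.trajectory.line_period,
        }
        f.attrs["trajectory_json"] = json.dumps(doc)
        if rec.crop_index is not None:
            f.attrs["crop_index"] = int(rec.crop_index)


def load_sls_recording(path) -> SLSRecording:
    with h5py.File(path, "r") as f:
        lines = f["lines"][...]
        timestamps = f["timestamps"][...]
        doc = json.loads(f.attrs["trajectory_json"])
        crop = int(f.attrs["crop_index"]) if "crop_index" in f.attrs else None
    coords = np.array([[r, c] for r, c, _ in doc["coords"]], dtype=int)
    labels = [_label_from_str(lab) for _, _, lab in doc["coords"]]
    refbox = tuple(doc["refbox"]) if doc.get("refbox") else None
    traj = SLSTrajectory(coords=coords, labels=labels,
                         line_period=float(doc["line_period"]), refbox=refbox)
    return SLSRecording(lines=lines, timestamps=timestamps, trajectory=traj,
                        crop_index=crop)


# ---------------------------------------------------------------------------
# SLS-as-raster embedding
# ---------------------------------------------------------------------------

def sls_to_raster(rec: SLSRecording, fov_shape: tuple[int, int], *,
                  seed: int, meta: Optional[AcquisitionMetadata] = None,
                  max_lines: Optional[int] = None) -> RasterMovie:
    """Embed an SLS recording into a raster movie, one frame per line.

    Trajectory pixels carry the recorded values; every other FOV pixel is an
    i.i.d. Gaussian draw with the mean and standard deviation of all recorded
    trajectory-pixel fluorescence, clipped at zero.  ``max_lines`` caps the
    number of embedded lines (memory guard for long recordings).
    """
    H, W = fov_shape
    coords = rec.trajectory.coords
    if (coords[:, 0].min() < 0 or coords[:, 1].min() < 0
            or coords[:, 0].max() >= H or coords[:, 1].max() >= W):
        raise DataError("trajectory coordinates fall outside the requested FOV")
    n = rec.n_lines if max_lines is None else min(rec.n_lines, max_lines)
    mu = float(rec.lines.mean())
    sd = float(rec.lines.std())
    rng = np.random.default_rng(seed)
    frames = rng.normal(mu, sd, size=(n, H, W)) if sd > 0 else np.full((n, H, W), mu)
    np.clip(frames, 0, None, out=frames)
    frames[:, coords[:, 0], coords[:, 1]] = rec.lines[:n]
    if meta is None:
        meta = AcquisitionMetadata(pixel_size=1.0,
                                   frame_period=rec.trajectory.line_period,
                                   line_period=rec.trajectory.line_period,
                                   dwell_time=1.0)
    return RasterMovie(frames=frames, meta=meta)
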
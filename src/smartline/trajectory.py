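"""Design of minimal-length smart-line-scan trajectories.

A trajectory visits every segmented ROI pixel once.  The ROI visiting order is
the (approximate) solution of a travelling-salesman problem over ROI centroids,
found with a genetic algorithm (population 100, 1000 generations; mutations:
flip, swap, slide; selection in random groups of 4 whose winner spawns the
group's next generation).  Within each ROI, pixels are chained by a greedy
nearest-neighbour walk.  An optional surround (Euclidean dilation of each ROI)
adds robustness pixels and neuropil estimators, and an optional reference box
scanned raster-like at the end of every pass supports planar motion estimation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist

from .errors import ConfigError, DataError
from .io import ROI, Segmentation, SLSTrajectory

__all__ = [
    "GAConfig",
    "OrderSolution",
    "solve_roi_order_ga",
    "brute_force_tsp",
    "greedy_intra_roi_path",
    "add_surround",
    "build_trajectory",
    "effective_line_rate",
]


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings for the centroid TSP."""

    population_size: int = 100
    n_generations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size <= 0 or self.n_generations <= 0:
            raise ConfigError("population size and generations must be positive")
        if self.population_size % 4 != 0:
            raise ConfigError("population size must be divisible by 4 "
                              "(selection works on groups of 4)")


@dataclass
class OrderSolution:
    """A closed-tour ordering of ROI indices and its length in pixels."""

    order: np.ndarray
    tour_length: float
    history: np.ndarray = field(default_factory=lambda: np.array([]))


def _tour_lengths(tours: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Closed-tour lengths for a [P, n] array of permutations."""
    p = pts[tours]                             # [P, n, 2]
    d = p - np.roll(p, -1, axis=1)
    return np.sqrt((d ** 2).sum(axis=2)).sum(axis=1)


def solve_roi_order_ga(centroids: Sequence[tuple[float, float]],
                       config: GAConfig = GAConfig()) -> OrderSolution:
    """Approximate the minimal closed tour over ROI centroids.

    Each generation evaluates all tour lengths, retains the global best seen so
    far, randomly partitions the population into groups of 4, and replaces each
    group by four variants of its winner: the winner itself plus one flip
    (reversal of a random subsegment), one swap (exchange of two random
    positions) and one slide (single-step rotation of a random subsegment).
    Fully reproducible from ``config.seed``.
    """
    pts = np.asarray(centroids, dtype=float)
    n = pts.shape[0]
    if n == 0:
        raise DataError("no centroids")
    if n <= 3:
        order = np.arange(n)
        length = float(_tour_lengths(order[None], pts)[0]) if n > 1 else 0.0
        return OrderSolution(order=order, tour_length=length,
                             history=np.full(config.n_generations, length))
    rng = np.random.default_rng(config.seed)
    P = config.population_size
    pop = np.array([rng.permutation(n) for _ in range(P)])
    lengths = _tour_lengths(pop, pts)
    best_i = int(np.argmin(lengths))
    best_len = float(lengths[best_i])
    best_order = pop[best_i].copy()
    history = np.empty(config.n_generations)

    for gen in range(config.n_generations):
        lengths = _tour_lengths(pop, pts)
        i = int(np.argmin(lengths))
        if lengths[i] < best_len:
            best_len = float(lengths[i])
            best_order = pop[i].copy()
        history[gen] = best_len
        perm = rng.permutation(P)
        new_pop = np.empty_like(pop)
        for g in range(P // 4):
            group = perm[4 * g: 4 * g + 4]
            winner = pop[group[np.argmin(lengths[group])]]
            i0, j0 = np.sort(rng.integers(0, n, size=2))
            a, b = rng.integers(0, n, size=2)
            k0, k1 = np.sort(rng.integers(0, n, size=2))
            base = 4 * g
            new_pop[base] = winner
            flip = winner.copy()
            flip[i0: j0 + 1] = flip[i0: j0 + 1][::-1]
            new_pop[base + 1] = flip
            swap = winner.copy()
            swap[[a, b]] = swap[[b, a]]
            new_pop[base + 2] = swap
            slide = winner.copy()
            slide[k0: k1 + 1] = np.roll(slide[k0: k1 + 1], 1)
            new_pop[base + 3] = slide
        pop = new_pop

    return OrderSolution(order=best_order, tour_length=best_len, history=history)


def brute_force_tsp(centroids: Sequence[tuple[float, float]]) -> OrderSolution:
    """Exact minimal closed tour by enumerating the (n-1)!/2 distinct tours
    (first node fixed, reversal symmetry halved).  Limited to n <= 10."""
    pts = np.asarray(centroids, dtype=float)
    n = pts.shape[0]
    if n > 10:
        raise ConfigError("brute force enumeration limited to n <= 10")
    if n == 0:
        raise DataError("no centroids")
    if n <= 3:
        order = np.arange(n)
        length = float(_tour_lengths(order[None], pts)[0]) if n > 1 else 0.0
        return OrderSolution(order=order, tour_length=length)
    best_order, best_len = None, np.inf
    for perm in itertools.permutations(range(1, n)):
        if perm[0] > perm[-1]:      # reversal symmetry
            continue
        tour = np.array((0,) + perm)
        length = float(_tour_lengths(tour[None], pts)[0])
        if length < best_len:
            best_len = length
            best_order = tour
    return OrderSolution(order=best_order, tour_length=best_len)


def greedy_intra_roi_path(pixels: Sequence[tuple[int, int]],
                          entry: tuple[float, float]) -> list[tuple[int, int]]:
    """Nearest-neighbour chain through a pixel set.

    Starts at the pixel closest to ``entry`` and repeatedly appends the nearest
    unvisited pixel (Euclidean); all distance ties break by (row, col)
    ascending.
    """
    pts = [(int(r), int(c)) for r, c in pixels]
    if not pts:
        raise DataError("empty pixel set")
    pts.sort()                      # tie-break order
    arr = np.asarray(pts, dtype=float)
    visited = np.zeros(len(pts), dtype=bool)
    d0 = np.hypot(arr[:, 0] - entry[0], arr[:, 1] - entry[1])
    cur = int(np.argmin(d0))        # argmin takes the first (lowest (row, col)) tie
    path = [pts[cur]]
    visited[cur] = True
    for _ in range(len(pts) - 1):
        d = np.hypot(arr[:, 0] - arr[cur, 0], arr[:, 1] - arr[cur, 1])
        d[visited] = np.inf
        cur = int(np.argmin(d))
        visited[cur] = True
        path.append(pts[cur])
    return path


def add_surround(seg: Segmentation, width: int) -> Segmentation:
    """Attach a surround footprint to each ROI: the Euclidean dilation of its
    pixel set by radius ``width``, minus all ROI pixels of any ROI, clipped to
    the FOV.  A pixel reached by two ROIs' dilations goes to the nearer ROI
    (ties to the lower ROI id)."""
    if width < 0:
        raise ConfigError("surround width must be >= 0")
    if width == 0:
        return Segmentation(fov_shape=seg.fov_shape,
                            rois=list(seg.rois), surround_width=0)
    H, W = seg.fov_shape
    any_roi = np.zeros((H, W), dtype=bool)
    for roi in seg.rois:
        any_roi[roi.pixels[:, 0], roi.pixels[:, 1]] = True
    by_id = sorted(seg.rois, key=lambda r: r.id)   # argmin tie -> lower ROI id
    dist = np.full((len(by_id), H, W), np.inf)
    for i, roi in enumerate(by_id):
        mask = np.zeros((H, W), dtype=bool)
        mask[roi.pixels[:, 0], roi.pixels[:, 1]] = True
        dist[i] = ndimage.distance_transform_edt(~mask)
    nearest = np.argmin(dist, axis=0)
    dmin = np.min(dist, axis=0)
    surrounds: dict[int, np.ndarray] = {}
    for i, roi in enumerate(by_id):
        sel = (nearest == i) & (dmin > 0) & (dmin <= width) & ~any_roi
        surrounds[roi.id] = np.argwhere(sel)
    return Segmentation(fov_shape=seg.fov_shape, rois=list(seg.rois),
                        surround_width=width, surrounds=surrounds)


def build_trajectory(seg: Segmentation, ga_config: GAConfig = GAConfig(),
                     surround_width: int = 0,
                     refbox: Optional[tuple[int, int, int, int]] = None,
                     line_period: Optional[float] = None,
                     dwell_time_us: float = 1.0,
                     flyback_us: float = 0.0) -> SLSTrajectory:
    """Build a full SLS trajectory from a segmentation.

    ROIs are visited in the GA tour order; within each ROI, its pixels and then
    (contiguously) its surround pixels follow a greedy nearest-neighbour chain
    whose entry point is the last pixel of the previous ROI (the first ROI
    enters at its own centroid).  Reference-box pixels are appended last in
    row-major order.  When ``line_period`` is not given it is derived from the
    pixel count, dwell time and flyback overhead.
    """
    if seg.n_rois < 1:
        raise DataError("segmentation has no ROIs")
    H, W = seg.fov_shape
    # reject overlapping ROI pixel sets
    seen: dict[tuple[int, int], int] = {}
    for roi in seg.rois:
        for p in roi.pixel_set():
            if p in seen:
                raise DataError(
                    f"ROI {roi.id} and ROI {seen[p]} share pixel {p}; "
                    "de-duplicate the segmentation before building a trajectory")
            seen[p] = roi.id
    if refbox is not None:
        r0, c0, h, w = refbox
        if r0 < 0 or c0 < 0 or h < 1 or w < 1 or r0 + h > H or c0 + w > W:
            raise DataError("reference box must lie inside the FOV")

    if surround_width > 0 and seg.surround_width != surround_width:
        seg = add_surround(seg, surround_width)

    centroids = [roi.centroid for roi in seg.rois]
    sol = solve_roi_order_ga(centroids, ga_config)

    coords: list[tuple[int, int]] = []
    labels: list[tuple[str, Optional[int]]] = []
    prev_pixel: Optional[tuple[int, int]] = None
    for idx in sol.order:
        roi = seg.rois[int(idx)]
        entry = prev_pixel if prev_pixel is not None else roi.centroid
        path = greedy_intra_roi_path([tuple(p) for p in roi.pixels], entry)
        coords.extend(path)
        labels.extend([("roi", roi.id)] * len(path))
        prev_pixel = path[-1]
        surr = seg.surrounds.get(roi.id)
        if surr is not None and len(surr) > 0:
            spath = greedy_intra_roi_path([tuple(p) for p in surr], prev_pixel)
            coords.extend(spath)
            labels.extend([("surround", roi.id)] * len(spath))
            prev_pixel = spath[-1]
    if refbox is not None:
        r0, c0, h, w = refbox
        for i in range(h):
            for j in range(w):
                coords.append((r0 + i, c0 + j))
                labels.append(("refbox", None))

    if line_period is None:
        line_period = 1.0 / _line_rate(len(coords), dwell_time_us, flyback_us)
    return SLSTrajectory(coords=np.array(coords, dtype=int), labels=labels,
                         line_period=line_period, refbox=refbox)


def _line_rate(n_pixels: int, dwell_time_us: float, flyback_us: float) -> float:
    return 1.0 / ((n_pixels * dwell_time_us + flyback_us) * 1e-6)


def effective_line_rate(traj: SLSTrajectory, dwell_time_us: float,
                        flyback_us: float = 0.0) -> float:
    """Sampling rate (Hz) of one trajectory pass: 1 / (n_pixels * dwell + flyback)."""
    if dwell_time_us <= 0:
        raise ConfigError("dwell time must be positive")
    return _line_rate(traj.n_pixels, dwell_time_us, flyback_us)
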
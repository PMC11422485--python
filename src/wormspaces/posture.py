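"""Frame-level posture extraction: contour, body ends, midline, curvature.

Each worm image is reduced to a closed contour (marching squares), the two
body ends (peaks of contour curvature), a 41-point equally spaced midline
(averaged head->tail splines of the two contour halves), and a 37-value
vector of signed midline turning angles.  Per-frame quality filters mirror
the tracking pipeline: multi-contour frames, high end-travel distance
ratios, runs of frames without a ratio, and overly round (curled) contours
are omitted from downstream analysis.

Coordinates follow the skimage convention (row, col); signed angles are
computed in the (x=col, y=row) plane with counter-clockwise positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import splev, splprep
from scipy.ndimage import convolve1d
from skimage import measure

__all__ = [
    "ContourError",
    "ContourFrame",
    "EndPair",
    "FrameQualityMask",
    "PostureResult",
    "extract_contour",
    "smooth_contour",
    "contour_curvature",
    "find_ends",
    "align_ends",
    "frame_quality",
    "compute_midline",
    "midline_turning_angles",
    "midline_curvature",
    "process_frames",
]

N_MIDLINE_POINTS = 41
N_RAW_ANGLES = N_MIDLINE_POINTS - 2       # 39 consecutive-triple angles
N_CURVATURE = N_RAW_ANGLES - 2            # 37 after trimming the noisy ends


class ContourError(RuntimeError):
    """Raised when no usable contour can be extracted from a frame."""


@dataclass
class ContourFrame:
    frame_index: int
    points: np.ndarray            # (n, 2) closed ring, CCW, last != first
    n_contours_detected: int

    @property
    def area(self) -> float:
        return abs(_signed_area(self.points))

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class EndPair:
    end1: np.ndarray              # (2,) coordinates
    end2: np.ndarray
    index1: int                   # contour point indices
    index2: int
    distance_ratio: float | None = None
    labels_swapped: bool = False


@dataclass
class FrameQualityMask:
    omitted: np.ndarray                       # (T,) bool
    reasons: dict[str, np.ndarray]            # reason code -> (T,) bool
    roundness: np.ndarray                     # (T,) float, NaN where undefined
    roundness_z: np.ndarray                   # (T,) float, NaN where undefined


def _signed_area(points: np.ndarray) -> float:
    """Shoelace area in the (x=col, y=row) plane; positive = CCW."""
    x = points[:, 1]
    y = points[:, 0]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def extract_contour(image: np.ndarray, level: float | None = None,
                    frame_index: int = 0) -> ContourFrame:
    """Extract the worm contour from one intensity image.

    Marching squares at ``level`` (default: midpoint of the image's dynamic
    range).  When several contours are found, the one with the most points
    is kept; the total count is recorded so multi-contour frames can be
    omitted downstream.  The ring is normalized to counter-clockwise
    orientation so downstream turning-angle signs are consistent.
    """
    img = np.asarray(image, dtype=float)
    if level is None:
        lo, hi = float(img.min()), float(img.max())
        if hi <= lo:
            raise ContourError("flat image, no contour")
        level = lo + 0.5 * (hi - lo)
    contours = measure.find_contours(img, level)
    if not contours:
        raise ContourError("no contour at threshold")
    best = max(contours, key=len)
    pts = np.asarray(best)
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise ContourError("degenerate contour")
    if _signed_area(pts) < 0:
        pts = pts[::-1].copy()
    return ContourFrame(frame_index, pts, len(contours))


def smooth_contour(points: np.ndarray, sigma_c: float = 2.0) -> np.ndarray:
    """Circularly convolve the contour ring with a normalized Gaussian."""
    if sigma_c <= 0:
        return np.asarray(points, dtype=float).copy()
    radius = max(1, int(np.ceil(4 * sigma_c)))
    x = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (x / sigma_c) ** 2)
    kernel /= kernel.sum()
    return convolve1d(np.asarray(points, dtype=float), kernel,
                      axis=0, mode="wrap")


def contour_curvature(points: np.ndarray) -> np.ndarray:
    """Signed turning angle at each contour point / half the neighbor chord.

    kappa_i = (angle turned at p_i under CCW traversal) / (|p_{i+1}-p_{i-1}|/2)
    with circular indexing.  Points with coincident neighbors get NaN.
    """
    p = np.asarray(points, dtype=float)
    prev = np.roll(p, 1, axis=0)
    nxt = np.roll(p, -1, axis=0)
    v1 = p - prev
    v2 = nxt - p
    # signed angle in (x=col, y=row) plane
    cross = v1[:, 1] * v2[:, 0] - v1[:, 0] * v2[:, 1]
    dot = (v1 * v2).sum(axis=1)
    angle = np.arctan2(cross, dot)
    chord = 0.5 * np.hypot(*(nxt - prev).T)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(chord > 0, angle / chord, np.nan)
    bad = (np.hypot(*v1.T) == 0) | (np.hypot(*v2.T) == 0)
    kappa[bad] = np.nan
    return kappa


def find_ends(kappa: np.ndarray, points: np.ndarray) -> EndPair:
    """Pick the two strict local curvature maxima with largest curvature.

    Ties are broken toward the lower contour index.  Raises ContourError if
    fewer than two strict local maxima exist (e.g. a perfect circle).
    """
    k = np.asarray(kappa, dtype=float)
    prev = np.roll(k, 1)
    nxt = np.roll(k, -1)
    with np.errstate(invalid="ignore"):
        is_peak = (k > prev) & (k > nxt)
    is_peak &= np.isfinite(k)
    idx = np.flatnonzero(is_peak)
    if len(idx) < 2:
        raise ContourError("fewer than two curvature peaks")
    # stable sort by descending curvature; ties keep lower index first
    order = idx[np.argsort(-k[idx], kind="stable")]
    i1, i2 = sorted(order[:2])
    return EndPair(points[i1].copy(), points[i2].copy(), int(i1), int(i2))


def align_ends(prev: EndPair, cur: EndPair) -> EndPair:
    """Keep end labels consistent across frames.

    The labels of the current frame's ends are swapped if swapping lowers
    the summed travel distance of the two ends since the previous (last
    successful) frame.  The distance ratio -- chosen sum over the
    alternative sum -- is recorded; it always lies in [0, 1].
    """
    d_keep = (np.hypot(*(cur.end1 - prev.end1)) +
              np.hypot(*(cur.end2 - prev.end2)))
    d_swap = (np.hypot(*(cur.end1 - prev.end2)) +
              np.hypot(*(cur.end2 - prev.end1)))
    if d_swap < d_keep:
        cur = EndPair(cur.end2, cur.end1, cur.index2, cur.index1,
                      labels_swapped=True)
        chosen, other = d_swap, d_keep
    else:
        chosen, other = d_keep, d_swap
    cur.distance_ratio = 0.0 if other == 0 else float(chosen / other)
    return cur


def _windowed_z(values: np.ndarray, window: int) -> np.ndarray:
    """Z-score of each value against mean/SD in [i-window, i+window].

    NaN entries are excluded from the window statistics and get NaN Z.
    A zero-SD window yields Z = 0.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    ok = np.isfinite(v)
    filled = np.where(ok, v, 0.0)
    cs = np.concatenate([[0.0], np.cumsum(filled)])
    cs2 = np.concatenate([[0.0], np.cumsum(filled ** 2)])
    cn = np.concatenate([[0], np.cumsum(ok.astype(int))])
    i = np.arange(n)
    lo = np.clip(i - window, 0, n)
    hi = np.clip(i + window + 1, 0, n)
    cnt = cn[hi] - cn[lo]
    s1 = cs[hi] - cs[lo]
    s2 = cs2[hi] - cs2[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = np.maximum(s2 / cnt - mean ** 2, 0.0)
        sd = np.sqrt(var)
        z = (v - mean) / sd
    z = np.where(sd == 0, 0.0, z)
    z[~ok | (cnt == 0)] = np.nan
    return z


def frame_quality(n_contours: np.ndarray,
                  distance_ratio: np.ndarray,
                  area: np.ndarray,
                  length: np.ndarray,
                  failed: np.ndarray | None = None,
                  ratio_threshold: float = 0.2,
                  z_threshold: float = 3.0,
                  z_window: int = 5000) -> FrameQualityMask:
    """Flag frames to omit, with one boolean vector per reason code.

    A frame is omitted iff at least one of these holds: (1) more than one
    contour was detected; (2) the distance ratio exceeds ``ratio_threshold``;
    (3) it belongs to a run of >= 2 consecutive frames with no distance
    ratio; (4) the roundness (interior area / contour length) Z-score,
    computed against frames i-z_window..i+z_window, exceeds ``z_threshold``;
    or extraction failed outright.
    """
    n_contours = np.asarray(n_contours)
    ratio = np.asarray(distance_ratio, dtype=float)
    area = np.asarray(area, dtype=float)
    length = np.asarray(length, dtype=float)
    T = len(ratio)
    if failed is None:
        failed = np.zeros(T, dtype=bool)
    failed = np.asarray(failed, dtype=bool)

    multi = n_contours > 1
    with np.errstate(invalid="ignore"):
        ratio_gt = np.isfinite(ratio) & (ratio > ratio_threshold)

    missing = ~np.isfinite(ratio)
    run = np.zeros(T, dtype=bool)
    start = None
    for i in range(T + 1):
        if i < T and missing[i]:
            if start is None:
                start = i
        elif start is not None:
            if i - start >= 2:
                run[start:i] = True
            start = None

    with np.errstate(invalid="ignore", divide="ignore"):
        roundness = np.where(length > 0, area / length, np.nan)
    z = _windowed_z(roundness, z_window)
    with np.errstate(invalid="ignore"):
        round_shape = np.isfinite(z) & (z > z_threshold)

    reasons = {
        "multi_contour": multi,
        "distance_ratio_gt": ratio_gt,
        "missing_ratio_run": run,
        "round_shape": round_shape,
        "extraction_failed": failed,
    }
    omitted = multi | ratio_gt | run | round_shape | failed
    return FrameQualityMask(omitted, reasons, roundness, z)


def _dedupe(points: np.ndarray) -> np.ndarray:
    keep = np.ones(len(points), dtype=bool)
    keep[1:] = np.any(np.diff(points, axis=0) != 0, axis=1)
    return points[keep]


def _fit_resample(points: np.ndarray, n: int, smooth: float = 0.0) -> np.ndarray:
    """Cubic spline through ``points`` (chord-length parameterized),
    sampled at n uniform parameter values.  ``smooth`` is the per-point
    smoothing budget handed to the spline fit (0 = interpolating)."""
    pts = _dedupe(np.asarray(points, dtype=float))
    if len(pts) < 2:
        raise ContourError("too few points for spline")
    seg = np.hypot(*np.diff(pts, axis=0).T)
    u = np.concatenate([[0.0], np.cumsum(seg)])
    if u[-1] == 0:
        raise ContourError("zero-length curve")
    u /= u[-1]
    k = min(3, len(pts) - 1)
    tck, _ = splprep(pts.T, u=u, s=smooth * len(pts), k=k)
    out = splev(np.linspace(0, 1, n), tck)
    return np.asarray(out).T


def compute_midline(contour: ContourFrame | np.ndarray, ends: EndPair,
                    n_points: int = N_MIDLINE_POINTS,
                    max_iter: int = 20, tol: float = 0.01,
                    contour_smooth: float = 0.09) -> np.ndarray:
    """41-point equally spaced midline from end1 (head side) to end2.

    The contour ring is split at the two ends; a chord-length cubic spline
    is fitted to each half (both oriented end1 -> end2, with a small
    smoothing budget ``contour_smooth`` per point to absorb rasterization
    stair-steps) and sampled at 41 equally spaced parameter values; the
    sample pairs are averaged, and the result is iteratively refit and
    resampled until the point spacing's coefficient of variation drops
    below ``tol`` (or ``max_iter``).
    """
    pts = contour.points if isinstance(contour, ContourFrame) else np.asarray(contour)
    i1, i2 = ends.index1, ends.index2
    n = len(pts)
    if i1 == i2:
        raise ContourError("ends coincide")
    idx_a = np.arange(i1, i1 + (i2 - i1) % n + 1) % n
    idx_b = np.arange(i2, i2 + (i1 - i2) % n + 1) % n
    half_a = pts[idx_a]
    half_b = pts[idx_b][::-1]          # reversed: also end1 -> end2
    try:
        sa = _fit_resample(half_a, n_points, smooth=contour_smooth)
        sb = _fit_resample(half_b, n_points, smooth=contour_smooth)
    except Exception as exc:           # spline failure -> frame failed
        raise ContourError(f"spline fitting failed: {exc}") from exc
    midline = 0.5 * (sa + sb)
    for _ in range(max_iter):
        seg = np.hypot(*np.diff(midline, axis=0).T)
        cv = seg.std() / seg.mean() if seg.mean() > 0 else np.inf
        if cv < tol:
            break
        midline = _fit_resample(midline, n_points)
    return midline


def midline_turning_angles(midline: np.ndarray) -> np.ndarray:
    """Signed angle at each interior midline point (39 values for 41 points).

    Positive = left turn when traversing head to tail in the (x=col, y=row)
    plane.  A straight midline gives all zeros; mirroring the worm negates
    every angle.
    """
    p = np.asarray(midline, dtype=float)
    v1 = p[1:-1] - p[:-2]
    v2 = p[2:] - p[1:-1]
    cross = v1[:, 1] * v2[:, 0] - v1[:, 0] * v2[:, 1]
    dot = (v1 * v2).sum(axis=1)
    return np.arctan2(cross, dot)


def midline_curvature(midline: np.ndarray) -> np.ndarray:
    """The 37-value curvature vector: 39 turning angles minus the two
    extreme points (which are noisiest near the worm's ends)."""
    return midline_turning_angles(midline)[1:-1]


@dataclass
class PostureResult:
    """Per-frame outputs of the posture stage for one recording."""

    curvature: np.ndarray             # (T, 37), NaN rows where failed
    end1: np.ndarray                  # (T, 2)
    end2: np.ndarray                  # (T, 2)
    distance_ratio: np.ndarray        # (T,), NaN where missing
    n_contours: np.ndarray            # (T,)
    area: np.ndarray                  # (T,)
    length: np.ndarray                # (T,)
    failed: np.ndarray                # (T,) bool
    midlines: np.ndarray | None = None  # (T, 41, 2) if stored
    quality: FrameQualityMask | None = field(default=None, repr=False)


def process_frames(images, level: float | None = None, sigma_c: float = 2.0,
                   store_midlines: bool = False,
                   ratio_threshold: float = 0.2, z_threshold: float = 3.0,
                   z_window: int = 5000) -> PostureResult:
    """Run the full per-frame posture pipeline over an image sequence.

    Yields curvature vectors in end1->end2 order (head orientation is
    resolved later, per segment) plus everything frame_quality needs.
    """
    images = list(images)
    T = len(images)
    curv = np.full((T, N_CURVATURE), np.nan)
    e1 = np.full((T, 2), np.nan)
    e2 = np.full((T, 2), np.nan)
    ratio = np.full(T, np.nan)
    ncont = np.zeros(T, dtype=int)
    area = np.full(T, np.nan)
    length = np.full(T, np.nan)
    failed = np.zeros(T, dtype=bool)
    mids = np.full((T, N_MIDLINE_POINTS, 2), np.nan) if store_midlines else None

    prev_ends: EndPair | None = None
    for t, img in enumerate(images):
        try:
            cf = extract_contour(img, level=level, frame_index=t)
            ncont[t] = cf.n_contours_detected
            area[t] = cf.area
            length[t] = cf.perimeter
            sm = smooth_contour(cf.points, sigma_c)
            kappa = contour_curvature(sm)
            ends = find_ends(kappa, sm)
            if prev_ends is not None:
                ends = align_ends(prev_ends, ends)
                ratio[t] = ends.distance_ratio
            # ends are found on the smoothed ring (stable peaks) but the
            # midline is fitted to the raw contour, whose tips are not
            # shrunk by the Gaussian smoothing; indices correspond 1:1
            midline = compute_midline(cf.points, ends)
            curv[t] = midline_curvature(midline)
            e1[t], e2[t] = ends.end1, ends.end2
            if mids is not None:
                mids[t] = midline
            prev_ends = ends
        except ContourError:
            failed[t] = True

    quality = frame_quality(ncont, ratio, area, length, failed,
                            ratio_threshold=ratio_threshold,
                            z_threshold=z_threshold, z_window=z_window)
    return PostureResult(curv, e1, e2, ratio, ncont, area, length, failed,
                         midlines=mids, quality=quality)
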
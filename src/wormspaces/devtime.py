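"""Developmental time: lethargus detection, stage boundaries, age bins.

Larval stage transitions are marked by lethargus -- developmentally timed
quiescence during molting -- detected as sustained dips in center-of-mass
speed.  Around each boundary guess t_k, speed is block-averaged (300-frame
blocks), converted to ECDF quantiles, smoothed across blocks, and the
maximal run of blocks below quantile 0.2 containing t_k is taken as the
lethargus interval.  Boundary k is the interval midpoint.  Each stage is
then split into 10 equal-time bins, giving 50 developmental bins, and
10-s posture windows are pooled per bin for the PCA stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .headtail import Segment

__all__ = [
    "LethargusInterval",
    "StageTimeline",
    "com_speed",
    "detect_lethargus",
    "stage_boundaries",
    "assign_bin",
    "assign_bins",
    "pool_windows",
]

N_STAGES = 5
BINS_PER_STAGE = 10
N_BINS = N_STAGES * BINS_PER_STAGE


@dataclass
class LethargusInterval:
    boundary_index: int          # k in 1..4
    start: int | None            # frames, inclusive / exclusive-end
    end: int | None
    failed: bool = False

    @property
    def midpoint(self) -> int | None:
        if self.failed or self.start is None:
            return None
        return (self.start + self.end) // 2


@dataclass
class StageTimeline:
    hatch: int
    boundaries: np.ndarray        # t_1..t_4
    end: int
    intervals: list[LethargusInterval] | None = None

    def __post_init__(self):
        t = np.asarray(self.boundaries)
        edges = np.concatenate([[self.hatch], t, [self.end]])
        if not np.all(np.diff(edges) > 0):
            raise ValueError("require hatch < t_1 < ... < t_4 < end")

    @property
    def stage_edges(self) -> np.ndarray:
        return np.concatenate([[self.hatch], np.asarray(self.boundaries),
                               [self.end]])


def com_speed(positions: np.ndarray, fps: float = 3.0) -> np.ndarray:
    """Speed estimate s_i = |p_{i+3} - p_i| from a (T, 2) COM trace.

    At 3 fps the 3-frame displacement spans one second, so the estimate is
    in pixels per second.  NaN positions propagate to NaN speeds; the last
    3 frames are NaN.
    """
    p = np.asarray(positions, dtype=float)
    gap = int(round(fps))
    s = np.full(len(p), np.nan)
    d = p[gap:] - p[:-gap]
    s[:-gap] = np.hypot(d[:, 0], d[:, 1])
    return s


def _smooth_renorm(x: np.ndarray, sigma: float) -> np.ndarray:
    radius = max(1, int(np.ceil(4 * sigma)))
    t = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detect_lethargus(speed: np.ndarray, hatch: int,
                     boundaries_guess: np.ndarray, end: int | None = None,
                     block: int = 300, q_thresh: float = 0.2,
                     sigma_blocks: float = 10.0) -> list[LethargusInterval]:
    """Detect one lethargus interval around each boundary guess.

    For boundary k the analysis range runs from a_k = 0.7 t_{k-1} + 0.3 t_k
    to b_k = 0.3 t_k + 0.7 t_{k+1} (t_0 = hatch, t_5 = recording end).
    Speed is averaged in consecutive non-overlapping ``block``-frame
    windows, each block mapped to its ECDF quantile among the range's
    blocks (missing blocks -> 1/2), the quantile series smoothed with a
    Gaussian of ``sigma_blocks`` blocks, and the lethargus marked as the
    maximal run of blocks with smoothed quantile < ``q_thresh`` containing
    t_k's block.  If t_k's own smoothed quantile is >= the threshold,
    detection fails for that boundary.
    """
    speed = np.asarray(speed, dtype=float)
    if end is None:
        end = len(speed)
    t = np.concatenate([[hatch], np.asarray(boundaries_guess, dtype=float),
                        [end]])
    if not np.all(np.diff(t) > 0):
        raise ValueError("boundary guesses must be strictly increasing")
    out = []
    for k in range(1, len(t) - 1):
        a = int(round(0.7 * t[k - 1] + 0.3 * t[k]))
        b = int(round(0.3 * t[k] + 0.7 * t[k + 1]))
        n_blocks = (b - a) // block
        if n_blocks < 1:
            out.append(LethargusInterval(k, None, None, failed=True))
            continue
        seg = speed[a:a + n_blocks * block].reshape(n_blocks, block)
        with np.errstate(invalid="ignore"):
            counts = np.isfinite(seg).sum(axis=1)
            sums = np.nansum(seg, axis=1)
            avgs = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        present = np.isfinite(avgs)
        q = np.full(n_blocks, 0.5)
        if present.any():
            vals = avgs[present]
            # right-continuous ECDF: fraction of blocks with average <= this
            q[present] = (vals[:, None] >= vals[None, :]).mean(axis=1)
        e = _smooth_renorm(q, sigma_blocks)
        tk_block = int(np.clip((t[k] - a) // block, 0, n_blocks - 1))
        if e[tk_block] >= q_thresh:
            out.append(LethargusInterval(k, None, None, failed=True))
            continue
        lo = tk_block
        while lo > 0 and e[lo - 1] < q_thresh:
            lo -= 1
        hi = tk_block
        while hi < n_blocks - 1 and e[hi + 1] < q_thresh:
            hi += 1
        out.append(LethargusInterval(k, a + lo * block,
                                     a + (hi + 1) * block - 1))
    return out


def stage_boundaries(intervals: list[LethargusInterval], hatch: int,
                     end: int) -> StageTimeline:
    """Stage timeline with boundaries at lethargus interval midpoints."""
    if any(iv.failed for iv in intervals):
        raise ValueError("lethargus detection failed for some boundary")
    mids = np.array([iv.midpoint for iv in intervals])
    return StageTimeline(hatch, mids, end, intervals=intervals)


def assign_bin(timeline: StageTimeline, frame: int) -> int:
    """Developmental bin index (1..50) of a frame.

    Stage s is the half-open interval [edge_{s-1}, edge_s); the bin within
    the stage is floor(10 * elapsed / stage length), clipped to 0..9.
    """
    edges = timeline.stage_edges
    if frame < edges[0] or frame >= edges[-1]:
        raise ValueError("frame outside [hatch, end)")
    s = int(np.searchsorted(edges, frame, side="right"))  # 1..5
    lo, hi = edges[s - 1], edges[s]
    b = int(np.clip(BINS_PER_STAGE * (frame - lo) // (hi - lo), 0,
                    BINS_PER_STAGE - 1))
    return BINS_PER_STAGE * (s - 1) + b + 1


def assign_bins(timeline: StageTimeline, n_frames: int) -> np.ndarray:
    """Vector of bin indices for frames 0..n_frames-1 (0 = outside)."""
    bins = np.zeros(n_frames, dtype=int)
    edges = timeline.stage_edges
    lo_all = max(int(edges[0]), 0)
    hi_all = min(int(edges[-1]), n_frames)
    for f in range(lo_all, hi_all):
        bins[f] = assign_bin(timeline, f)
    return bins


def pool_windows(curvature: np.ndarray, segments: list[Segment],
                 bins: np.ndarray, window_s: float = 10.0, fps: float = 3.0,
                 ) -> dict[int, np.ndarray]:
    """Pool all overlapping posture-dynamics windows per developmental bin.

    A window of T_w = round(window_s * fps) frames contributes iff it lies
    entirely inside a single segment that passed the head-confidence
    threshold; it is assigned to the bin of its start frame and flattened
    (time-major) to a length 37*T_w vector.  Returns bin -> (n_windows,
    37*T_w) array.
    """
    t_w = int(round(window_s * fps))
    k = curvature.shape[1]
    pools: dict[int, list[np.ndarray]] = {}
    for seg in segments:
        if not seg.passes_threshold:
            continue
        for start in range(seg.start, seg.end - t_w + 2):
            b = int(bins[start])
            if b <= 0:
                continue
            win = curvature[start:start + t_w]
            if np.isnan(win).any():
                continue
            pools.setdefault(b, []).append(win.reshape(t_w * k))
    return {b: np.asarray(v) for b, v in sorted(pools.items())}
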
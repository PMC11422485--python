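"""Head-tail disambiguation from end-point kinematics.

Time is divided into segments of consecutive non-omitted frames; within
each segment the head is identified as the end with faster side-to-side
movement: the two end trajectories are Gaussian-smoothed, per-frame speeds
estimated by central differences, and the head chosen by the sign of the
mean log speed ratio.  Its absolute value serves as a confidence measure;
segments with confidence <= 0.05 are excluded from downstream pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Segment", "segment_frames", "classify_head", "classify_segments",
           "orient_curvature", "segments_to_frame"]

DEFAULT_CONF_THRESHOLD = 0.05


@dataclass
class Segment:
    start: int                      # inclusive frame indices
    end: int
    head_label: int | None = None   # 1 or 2
    confidence: float = np.nan
    passes_threshold: bool = False

    def __len__(self) -> int:
        return self.end - self.start + 1


def segment_frames(omitted: np.ndarray) -> list[Segment]:
    """Maximal runs of consecutive non-omitted frames, in order."""
    omitted = np.asarray(omitted, dtype=bool)
    segments = []
    start = None
    for i in range(len(omitted) + 1):
        if i < len(omitted) and not omitted[i]:
            if start is None:
                start = i
        elif start is not None:
            segments.append(Segment(start, i - 1))
            start = None
    return segments


def _smooth_renorm(x: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing with a truncated, edge-renormalized kernel."""
    if sigma <= 0 or len(x) < 2:
        return np.asarray(x, dtype=float).copy()
    radius = max(1, int(np.ceil(4 * sigma)))
    t = np.arange(-radius, radius + 1, dtype=float)
    kernel = np.exp(-0.5 * (t / sigma) ** 2)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x, dtype=float), kernel, mode="same")
    return num / den


def classify_head(segment: Segment, end1: np.ndarray, end2: np.ndarray,
                  sigma: float = 5.0,
                  conf_threshold: float = DEFAULT_CONF_THRESHOLD) -> Segment:
    """Label the faster-moving end of a segment as the head.

    ``end1``/``end2`` are (T, 2) whole-recording coordinate tracks.  Within
    the segment each coordinate is smoothed (sigma in frames); the speed of
    end j at frame i is |e_{i+1} - e_{i-1}|/2 and the log speed ratio
    lsr_i = ln(s1_i / s2_i).  Head = end1 if the segment-mean lsr is
    positive, end2 if negative.  Confidence = |mean lsr|; the segment
    passes iff confidence strictly exceeds ``conf_threshold``.  Frames
    where either speed is zero are excluded from the mean.
    """
    s, e = segment.start, segment.end
    if e - s + 1 < 3:
        segment.head_label = None
        segment.confidence = 0.0
        segment.passes_threshold = False
        return segment
    tracks = []
    for track in (end1, end2):
        sm = np.column_stack([
            _smooth_renorm(track[s:e + 1, 0], sigma),
            _smooth_renorm(track[s:e + 1, 1], sigma),
        ])
        speed = 0.5 * np.hypot(*(sm[2:] - sm[:-2]).T)
        tracks.append(speed)
    s1, s2 = tracks
    valid = (s1 > 0) & (s2 > 0)
    if not valid.any():
        mean_lsr = 0.0
    else:
        mean_lsr = float(np.mean(np.log(s1[valid] / s2[valid])))
    if mean_lsr > 0:
        segment.head_label = 1
    elif mean_lsr < 0:
        segment.head_label = 2
    else:
        segment.head_label = None
    segment.confidence = abs(mean_lsr)
    segment.passes_threshold = segment.confidence > conf_threshold
    return segment


def classify_segments(omitted: np.ndarray, end1: np.ndarray, end2: np.ndarray,
                      sigma: float = 5.0,
                      conf_threshold: float = DEFAULT_CONF_THRESHOLD,
                      ) -> list[Segment]:
    """segment_frames + classify_head over a whole recording."""
    segments = segment_frames(omitted)
    for seg in segments:
        classify_head(seg, end1, end2, sigma=sigma,
                      conf_threshold=conf_threshold)
    return segments


def orient_curvature(curvature: np.ndarray, segments: list[Segment],
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Apply per-segment head labels so curvature rows run head -> tail.

    Rows in segments whose head is end2 are reversed along the body axis
    and sign-flipped (traversing the midline backwards mirrors every
    turning angle).  Returns (oriented matrix, per-frame validity mask);
    frames outside passing segments are invalid.
    """
    oriented = np.array(curvature, dtype=float, copy=True)
    valid = np.zeros(len(oriented), dtype=bool)
    for seg in segments:
        if not seg.passes_threshold or seg.head_label is None:
            continue
        sl = slice(seg.start, seg.end + 1)
        if seg.head_label == 2:
            oriented[sl] = -oriented[sl, ::-1]
        valid[sl] = True
    valid &= ~np.isnan(oriented).any(axis=1)
    return oriented, valid


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    """Segment table (start, end, head_label, confidence, passes)."""
    return pd.DataFrame(
        {
            "start": [s.start for s in segments],
            "end": [s.end for s in segments],
            "head_label": [s.head_label for s in segments],
            "confidence": [s.confidence for s in segments],
            "passes": [s.passes_threshold for s in segments],
        }
    )
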
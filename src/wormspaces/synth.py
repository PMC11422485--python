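"""Synthetic data with planted ground truth for every pipeline stage.

Three generators emulate the structure the analysis assumes, each serialized
with its truth so parameter-recovery tests can score the pipeline:

* worm image sequences -- an undulating, tapered body rendered into binary
  frames, with the known 41-point midline and head identity per frame; the
  head end carries extra side-to-side oscillation so head-tail
  classification is well-posed;
* posture-dynamics window populations -- low-rank Gaussian windows whose
  population modes follow a smooth geodesic rotation across developmental
  bins (so inter-bin subspace distance grows with temporal lag), plus
  individual-specific unique modes with controllable magnitude eta and
  cross-bin consistency;
* center-of-mass traces -- a heading random walk whose speed drops from the
  active to the quiescent level inside lethargus episodes around each stage
  boundary.

All generators are fully reproducible from (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WormShapeParams",
    "simulate_worm_frames",
    "simulate_end_tracks",
    "grassmann_geodesic",
    "random_orthonormal",
    "simulate_planted_rank",
    "PopulationTruth",
    "simulate_population",
    "simulate_com_trace",
    "simulate_rank_null",
]

FPS = 3.0


# ---------------------------------------------------------------------------
# worm image rendering

@dataclass
class WormShapeParams:
    """Geometry and kinematics of the rendered worm.

    Lengths are in pixels, times in frames (3 fps).  The head-end extra
    curvature oscillation makes the head tip move faster side-to-side than
    the tail whenever ``head_wiggle_amp`` > 0.
    """

    length: float = 80.0
    max_half_width: float = 4.5
    image_size: int = 128
    wave_amp: float = 2.0            # rad per unit arc length
    wave_freq: float = 1.5           # spatial periods along the body
    phase_speed: float = 0.06        # rad per frame
    head_wiggle_amp: float = 6.0     # rad per unit arc length, at the tip
    head_wiggle_decay: float = 0.25  # e-folding length (fraction of body)
    head_wiggle_period: float = 30.0  # frames
    com_speed: float = 0.3           # px per frame
    com_max_offset: float = 8.0      # px; frames emulate a tracking crop,
                                     # so the COM stays near the center
    noise: float = 0.0               # binary pixel flip probability


def _worm_midline(params: WormShapeParams, t: float, n_points: int,
                  heading0: float, com: np.ndarray) -> np.ndarray:
    """Midline points (n_points, 2) in (x, y), head first, equal spacing."""
    s = np.linspace(0.0, 1.0, n_points)
    ds = 1.0 / (n_points - 1)
    kappa = (params.wave_amp
             * np.sin(2 * np.pi * params.wave_freq * s - params.phase_speed * t)
             + params.head_wiggle_amp
             * np.exp(-s / params.head_wiggle_decay)
             * np.sin(2 * np.pi * t / params.head_wiggle_period))
    # integrate heading outward from the body midpoint so neither end
    # accumulates the whole wave; the head-end wiggle term then dominates
    # the head tip's side-to-side motion
    mid = n_points // 2
    heading = np.empty(n_points)
    heading[mid] = heading0
    heading[mid:] = heading0 + np.concatenate(
        [[0.0], np.cumsum(kappa[mid + 1:]) * ds])
    heading[:mid] = heading0 - np.cumsum(kappa[mid - 1::-1] * ds)[::-1]
    steps = params.length * ds * np.column_stack([np.cos(heading),
                                                  np.sin(heading)])
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps[:-1], axis=0)])
    pts = pts - pts.mean(axis=0) + com
    return pts


def _width_profile(s: np.ndarray, max_half_width: float) -> np.ndarray:
    return max_half_width * np.sin(np.pi * s) ** 0.6


def render_worm(midline: np.ndarray, max_half_width: float,
                image_size: int) -> np.ndarray:
    """Rasterize a midline into a binary image: pixels within the local
    half-width of the midline polyline are foreground."""
    from scipy.spatial import cKDTree

    n = len(midline)
    s = np.linspace(0.0, 1.0, n)
    w = _width_profile(s, max_half_width)
    img = np.zeros((image_size, image_size))
    pad = max_half_width + 2
    x0 = int(np.clip(midline[:, 0].min() - pad, 0, image_size))
    x1 = int(np.clip(midline[:, 0].max() + pad + 1, 0, image_size))
    y0 = int(np.clip(midline[:, 1].min() - pad, 0, image_size))
    y1 = int(np.clip(midline[:, 1].max() + pad + 1, 0, image_size))
    if x1 <= x0 or y1 <= y0:
        return img
    yy, xx = np.mgrid[y0:y1, x0:x1]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    # distance to nearest midline sample and that sample's half-width
    dist, nearest = cKDTree(midline).query(pix)
    inside = dist <= w[nearest]
    img[y0:y1, x0:x1] = inside.reshape(y1 - y0, x1 - x0)
    return img


def simulate_worm_frames(params: WormShapeParams | None = None,
                         n_frames: int = 30,
                         seed: int | np.random.Generator | None = 0,
                         n_midline_points: int = 41,
                         curl_frames: tuple[int, ...] = (),
                         ) -> tuple[np.ndarray, dict]:
    """Render a moving undulating worm; returns (frames, truth).

    ``truth`` holds the 41-point ground-truth midline per frame in
    (row, col) coordinates (head first), the head coordinate, and the
    frames replaced by a curled-up disk (for quality-filter tests).
    """
    params = params or WormShapeParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    size = params.image_size
    center = np.array([size / 2.0, size / 2.0])
    heading0 = rng.uniform(0, 2 * np.pi)
    com_dir = rng.uniform(0, 2 * np.pi)
    frames = np.zeros((n_frames, size, size))
    midlines = np.full((n_frames, n_midline_points, 2), np.nan)
    dense_n = 121
    offset = np.zeros(2)
    for t in range(n_frames):
        com_dir += rng.normal(0, 0.2)
        step = params.com_speed * np.array([np.cos(com_dir), np.sin(com_dir)])
        if np.linalg.norm(offset + step) > params.com_max_offset:
            com_dir += np.pi          # bounce back toward the center
            step = -step
        offset = offset + step
        com = center + offset
        if t in curl_frames:
            yy, xx = np.mgrid[0:size, 0:size]
            r = params.length / (2 * np.pi) * 1.5
            frames[t] = ((xx - com[0]) ** 2 + (yy - com[1]) ** 2
                         <= r ** 2).astype(float)
            continue
        dense = _worm_midline(params, t, dense_n, heading0, com)
        frames[t] = render_worm(dense, params.max_half_width, size)
        if params.noise > 0:
            flip = rng.random((size, size)) < params.noise
            frames[t] = np.where(flip, 1 - frames[t], frames[t])
        idx = np.linspace(0, dense_n - 1, n_midline_points).round().astype(int)
        midlines[t] = dense[idx][:, ::-1]         # (x, y) -> (row=y, col=x)
    truth = {"midlines": midlines, "head": midlines[:, 0, :],
             "curl_frames": tuple(curl_frames), "params": params}
    return frames, truth


def simulate_end_tracks(n_frames: int = 300, head_amp: float = 5.0,
                        amplitude_ratio: float = 3.0, period: float = 24.0,
                        body_length: float = 60.0, com_speed: float = 0.3,
                        noise: float = 0.1, head_is_end1: bool = True,
                        seed: int | np.random.Generator | None = 0,
                        ) -> tuple[np.ndarray, np.ndarray, dict]:
    """End-point coordinate tracks with a faster-oscillating head.

    Both ends oscillate perpendicular to the body axis at the same period
    (so Gaussian smoothing attenuates them equally) with amplitudes
    ``head_amp`` and ``head_amp / amplitude_ratio``.  Returns
    (end1, end2, truth) where truth records which label is the head.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(n_frames)
    heading = np.cumsum(rng.normal(0, 0.02, n_frames))
    com = np.cumsum(com_speed * np.column_stack([np.cos(heading),
                                                 np.sin(heading)]), axis=0)
    axis = np.column_stack([np.cos(heading), np.sin(heading)])
    perp = np.column_stack([-np.sin(heading), np.cos(heading)])
    ph, pt = rng.uniform(0, 2 * np.pi, 2)
    tail_amp = head_amp / amplitude_ratio
    head = (com + 0.5 * body_length * axis
            + head_amp * np.sin(2 * np.pi * t / period + ph)[:, None] * perp
            + rng.normal(0, noise, (n_frames, 2)))
    tail = (com - 0.5 * body_length * axis
            + tail_amp * np.sin(2 * np.pi * t / period + pt)[:, None] * perp
            + rng.normal(0, noise, (n_frames, 2)))
    end1, end2 = (head, tail) if head_is_end1 else (tail, head)
    truth = {"head_label": 1 if head_is_end1 else 2}
    return end1, end2, truth


# ---------------------------------------------------------------------------
# posture-dynamics window populations

def random_orthonormal(p: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """Random p x d matrix with orthonormal columns (QR of a Gaussian)."""
    q, r = np.linalg.qr(rng.standard_normal((p, d)))
    return q * np.sign(np.diag(r))


def grassmann_geodesic(B0: np.ndarray, B1: np.ndarray,
                       t: float) -> np.ndarray:
    """Point at fraction t along the geodesic from span(B0) to span(B1).

    B0, B1 are p x d with orthonormal columns; the result is orthonormal
    and equals B0 at t=0 and a basis of span(B1) at t=1.
    """
    M = B0.T @ B1
    F = (B1 - B0 @ M) @ np.linalg.inv(M)
    U, sig, Vt = np.linalg.svd(F, full_matrices=False)
    theta = np.arctan(sig)
    return (B0 @ Vt.T * np.cos(t * theta) + U * np.sin(t * theta)) @ Vt


def simulate_planted_rank(n_windows: int, rank: int, snr: float = 100.0,
                          n_features: int | None = None, window_s: float = 10.0,
                          fps: float = FPS, n_curv: int = 37,
                          seed: int | np.random.Generator | None = 0,
                          ) -> tuple[np.ndarray, dict]:
    """Windows drawn from an exact-rank linear model plus isotropic noise.

    Planted modes have unit variance each; the noise variance per feature
    is (total signal variance) / (snr * n_features), so ``snr`` is the
    total signal-to-noise variance ratio.  Returns (windows, truth).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = n_features or int(round(window_s * fps)) * n_curv
    modes = random_orthonormal(p, rank, rng)
    z = rng.standard_normal((n_windows, rank))
    sigma = np.sqrt(rank / (snr * p))
    X = z @ modes.T + sigma * rng.standard_normal((n_windows, p))
    return X, {"modes": modes, "rank": rank, "noise_sd": sigma}


@dataclass
class PopulationTruth:
    """Planted structure of a simulated population."""

    pop_bases: np.ndarray            # (n_bins, p, d_true)
    variances: np.ndarray            # (d_true,) population mode variances
    eta: np.ndarray                  # (n_individuals,) uniqueness magnitudes
    unique_bases: dict = field(repr=False, default_factory=dict)
    consistent: np.ndarray | None = None
    d_true: int = 0
    noise_sd: float = 0.0
    seed: int | None = None


def simulate_population(n_individuals: int = 24, n_bins: int = 50,
                        d_true: int = 5, windows_per_bin: int = 50,
                        window_s: float = 10.0, fps: float = FPS,
                        n_curv: int = 37, snr: float = 100.0,
                        eta: np.ndarray | None = None,
                        unique_dim: int = 2, unique_var: float | None = None,
                        consistent: bool | np.ndarray = True,
                        drift_angle_scale: float = 1.0,
                        seed: int | np.random.Generator | None = 0,
                        ) -> tuple[dict, PopulationTruth]:
    """Per-individual, per-bin window pools with planted structure.

    Windows are drawn as (population modes @ z) + eta_i * (unique modes
    @ z') + isotropic noise.  Population modes follow a geodesic rotation
    across bins so the subspace distance between bins grows with temporal
    lag; mode variances decay geometrically.  ``eta`` defaults to values
    evenly spread over [0, 1]; consistent individuals keep the same unique
    modes in every bin, inconsistent ones redraw them per bin.

    Returns (pools, truth) where pools[i][b] is the (windows_per_bin, p)
    array for individual i (0-based) in bin b (1-based).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = int(round(window_s * fps)) * n_curv
    variances = 0.8 ** np.arange(d_true)
    sigma = np.sqrt(variances.sum() / (snr * p))
    if eta is None:
        eta = (np.linspace(0, 1, n_individuals) if n_individuals > 1
               else np.zeros(1))
    eta = np.asarray(eta, dtype=float)
    if np.isscalar(consistent) or isinstance(consistent, bool):
        consistent = np.full(n_individuals, bool(consistent))
    consistent = np.asarray(consistent, dtype=bool)
    if unique_var is None:
        # half the mean population-mode variance: per-individual modes are
        # conspicuous within that individual's own windows yet remain a
        # small fraction of the pooled population variance (each individual
        # contributes only 1/n of the pool), as in large real populations
        unique_var = 0.5 * float(variances.mean())

    B_start = random_orthonormal(p, d_true, rng)
    B_end = random_orthonormal(p, d_true, rng)
    ts = (np.linspace(0, 1, n_bins) * drift_angle_scale if n_bins > 1
          else np.zeros(1))
    pop_bases = np.stack([grassmann_geodesic(B_start, B_end, t) for t in ts])

    fixed_unique = {i: random_orthonormal(p, unique_dim, rng)
                    for i in range(n_individuals)}
    pools: dict[int, dict[int, np.ndarray]] = {i: {} for i in range(n_individuals)}
    unique_record: dict[tuple[int, int], np.ndarray] = {}
    sd = np.sqrt(variances)
    u_sd = np.sqrt(unique_var)
    for b in range(n_bins):
        B = pop_bases[b]
        for i in range(n_individuals):
            if consistent[i]:
                Ui = fixed_unique[i]
            else:
                Ui = random_orthonormal(p, unique_dim, rng)
            unique_record[(i, b + 1)] = Ui
            z = rng.standard_normal((windows_per_bin, d_true)) * sd
            zu = rng.standard_normal((windows_per_bin, unique_dim)) * u_sd
            X = (z @ B.T + eta[i] * (zu @ Ui.T)
                 + sigma * rng.standard_normal((windows_per_bin, p)))
            pools[i][b + 1] = X
    truth = PopulationTruth(pop_bases, variances, eta, unique_record,
                            consistent, d_true, float(sigma))
    return pools, truth


def population_pool(pools: dict, bin_index: int) -> np.ndarray:
    """Stack every individual's windows for one bin (the population pool)."""
    return np.vstack([pools[i][bin_index] for i in sorted(pools)
                      if bin_index in pools[i]])


# ---------------------------------------------------------------------------
# center-of-mass traces with lethargus dips

DEFAULT_STAGE_HOURS = (14.0, 9.0, 9.0, 10.0, 16.0)
DEFAULT_LETHARGUS_HOURS = 2.0


def simulate_com_trace(stage_lengths: tuple[int, ...] | None = None,
                       lethargus_lengths: tuple[int, ...] | None = None,
                       active_speed: float = 18.0,
                       quiescent_speed: float = 0.5,
                       speed_cv: float = 0.3,
                       heading_sigma: float = 0.05,
                       fps: float = FPS,
                       gap_fraction: float = 0.0,
                       seed: int | np.random.Generator | None = 0,
                       ) -> tuple[np.ndarray, dict]:
    """COM positions whose speed dips inside lethargus episodes.

    ``stage_lengths`` are the 5 stage durations in frames (default:
    biologically plausible hours at 3 fps) and ``lethargus_lengths`` the
    4 episode durations in frames (default 2 h each), centered on the
    stage boundaries.  Speeds are in px/s; per-frame multiplicative noise
    has coefficient of variation ``speed_cv``.  Optional tracking gaps
    replace random runs of positions with NaN.

    Returns (positions, truth) with truth boundaries t_1..t_4, lethargus
    intervals, hatch=0 and the recording end.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if stage_lengths is None:
        stage_lengths = tuple(int(h * 3600 * fps) for h in DEFAULT_STAGE_HOURS)
    if lethargus_lengths is None:
        L = int(DEFAULT_LETHARGUS_HOURS * 3600 * fps)
        lethargus_lengths = (L, L, L, L)
    edges = np.concatenate([[0], np.cumsum(stage_lengths)])
    boundaries = edges[1:5]
    T = int(edges[-1])
    intervals = [(int(t - l // 2), int(t + l // 2))
                 for t, l in zip(boundaries, lethargus_lengths)]
    speed = np.full(T, float(active_speed))
    for lo, hi in intervals:
        speed[max(lo, 0):min(hi, T)] = quiescent_speed
    speed = speed * np.clip(1 + speed_cv * rng.standard_normal(T), 0.05, None)
    heading = np.cumsum(rng.normal(0, heading_sigma, T))
    steps = (speed / fps)[:, None] * np.column_stack([np.cos(heading),
                                                      np.sin(heading)])
    positions = np.cumsum(steps, axis=0)
    if gap_fraction > 0:
        n_gaps = max(1, int(gap_fraction * T / 600))
        for _ in range(n_gaps):
            start = rng.integers(0, T - 600)
            positions[start:start + 600] = np.nan
    truth = {"hatch": 0, "boundaries": boundaries.astype(int), "end": T,
             "intervals": intervals}
    return positions, truth


# ---------------------------------------------------------------------------
# rank-level null

def simulate_rank_null(n_individuals: int, n_bins: int,
                       seed: int | np.random.Generator | None = 0,
                       ) -> np.ndarray:
    """Exchangeable null distances (individuals x bins): iid uniforms.

    Distributionally equivalent, at the rank level, to running the full
    pipeline on a population with no planted individuality (eta = 0).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.random((n_individuals, n_bins))
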
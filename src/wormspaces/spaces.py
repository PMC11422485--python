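"""Behavioral spaces: pooled-window PCA and cross-validated dimensionality.

A behavioral space is the PCA of a pool of flattened posture-dynamics
windows: its orthonormal loading vectors are the dominant movement modes in
one developmental bin, the associated variances say how much each mode is
used, and the estimated dimensionality says how many modes are supported by
held-out data.

Dimensionality is estimated by bi-cross-validation of the window matrix
M (features x windows): rows and columns are held out independently with
probability p, M is partitioned as [[A, B], [C, D]] with A the held-out
block, a truncated SVD of D provides axes and scores, held-out scores and
axes are obtained by least squares, and the relative reconstruction error
of A is traced against the dimensionality d.  The chosen d is the last
dimension whose addition still decreased log10(error) by at least delta,
bootstrap-averaged over repeated holdouts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.decomposition import PCA as _SkPCA

__all__ = [
    "BehaviorSpace",
    "fit_space",
    "cv_error",
    "estimate_dimensionality",
    "individual_dimensionality",
    "reconstruct_window",
]


@dataclass
class BehaviorSpace:
    """Mean, orthonormal loadings, variances and dimensionality of one pool."""

    mean: np.ndarray                 # (p,)
    loadings: np.ndarray             # (p, m), orthonormal columns
    variances: np.ndarray            # (m,), non-increasing score variances
    total_variance: float            # sum over ALL features of pooled variance
    n_windows: int
    d: int | None = None             # estimated dimensionality
    bin_index: int | None = None
    label: str | None = None
    meta: dict = field(default_factory=dict, repr=False)

    @property
    def n_features(self) -> int:
        return self.mean.shape[0]

    @property
    def degenerate(self) -> bool:
        return self.total_variance <= 0

    def variance_share(self) -> np.ndarray:
        """Cumulative fraction of total variance explained by the first m."""
        if self.total_variance <= 0:
            return np.ones_like(self.variances)
        return np.cumsum(self.variances) / self.total_variance

    def truncated(self, d: int) -> tuple[np.ndarray, np.ndarray]:
        """(loadings, variances) restricted to the top d components."""
        d = min(d, self.loadings.shape[1])
        return self.loadings[:, :d], self.variances[:d]


def fit_space(pool: np.ndarray, n_components: int | None = None,
              random_state: int = 0, **meta) -> BehaviorSpace:
    """Mean-centered PCA of a pool of windows (rows = windows).

    With ``n_components=None`` all components up to the matrix rank are
    kept (economy SVD); otherwise sklearn's randomized solver computes a
    truncated fit.  Score variances use the n-1 normalization; their sum
    over all components equals the total pooled variance.
    """
    X = np.asarray(pool, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 windows to fit a space")
    n, p = X.shape
    mean = X.mean(axis=0)
    Xc = X - mean
    total = float((Xc ** 2).sum() / (n - 1))
    m_max = min(n - 1, p)
    if n_components is None or n_components >= m_max:
        _, s, vt = linalg.svd(Xc, full_matrices=False)
        s, vt = s[:m_max], vt[:m_max]
        loadings = vt.T
        variances = s ** 2 / (n - 1)
    else:
        pca = _SkPCA(n_components=n_components, svd_solver="randomized",
                     random_state=random_state)
        pca.fit(X)
        loadings = pca.components_.T
        variances = pca.explained_variance_
    return BehaviorSpace(mean, loadings, variances, total, n,
                         bin_index=meta.pop("bin_index", None),
                         label=meta.pop("label", None), meta=meta)


def _holdout_masks(n_rows: int, n_cols: int, p: float,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    return rng.random(n_rows) < p, rng.random(n_cols) < p


def cv_error(M: np.ndarray, d, holdout_p: float = 0.1,
             rng: np.random.Generator | int | None = None,
             row_mask: np.ndarray | None = None,
             col_mask: np.ndarray | None = None,
             max_redraw: int = 100):
    """Bi-cross-validation reconstruction error(s) for one holdout draw.

    ``M`` is features x windows.  ``d`` may be an int or a 1-D array of
    candidate dimensionalities; the same holdout is used for all of them.
    Each row/column is held out independently with probability
    ``holdout_p``; degenerate draws (empty held-out block, too-small kept
    block, or a constant A) are redrawn from the RNG stream.  Explicit
    ``row_mask``/``col_mask`` bypass the drawing (no redraw).

    For dimensionality q of the kept block D = U S V^T, candidate d > q
    uses only the available q components.
    """
    M = np.asarray(M, dtype=float)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    d_arr = np.atleast_1d(np.asarray(d, dtype=int))
    scalar = np.isscalar(d) or np.asarray(d).ndim == 0

    explicit = row_mask is not None or col_mask is not None
    for _ in range(max_redraw):
        if not explicit:
            row_mask, col_mask = _holdout_masks(M.shape[0], M.shape[1],
                                                holdout_p, rng)
        rm = np.asarray(row_mask, dtype=bool)
        cm = np.asarray(col_mask, dtype=bool)
        A = M[np.ix_(rm, cm)]
        D = M[np.ix_(~rm, ~cm)]
        denom = float(((A - A.mean()) ** 2).sum()) if A.size else 0.0
        if (A.size == 0 or D.shape[0] < 2 or D.shape[1] < 2 or denom <= 0):
            if explicit:
                raise ValueError("degenerate explicit holdout")
            continue
        B = M[np.ix_(rm, ~cm)]
        C = M[np.ix_(~rm, cm)]
        u, s, vt = linalg.svd(D, full_matrices=False)
        q = int((s > s[0] * 1e-12).sum()) if s.size else 0
        # A_hat(d) = sum_{j<=d} (B v_j) s_j^{-1} (u_j^T C)
        P = B @ vt[:q].T                    # (r_out, q)
        Q = u[:, :q].T @ C                  # (q, c_out)
        R = A.copy()
        resid_at = {}
        for dd in range(1, int(d_arr.max()) + 1):
            if dd <= q:
                R -= np.outer(P[:, dd - 1] / s[dd - 1], Q[dd - 1])
            resid_at[dd] = float((R ** 2).sum())
        errs = np.array([resid_at[max(int(dd), 1)] / denom for dd in d_arr])
        return float(errs[0]) if scalar else errs
    raise RuntimeError("could not draw a non-degenerate holdout")


def estimate_dimensionality(pool: np.ndarray, d_max: int = 50,
                            n_sample: int = 1000, repeats: int = 10,
                            n_boot: int = 10000, delta: float = 0.01,
                            holdout_p: float = 0.1,
                            rng: np.random.Generator | int | None = None,
                            return_info: bool = False):
    """Bootstrap estimate of the number of significant PCA dimensions.

    ``pool`` is windows x features.  n_sample windows are drawn without
    replacement (all windows if the pool is smaller), ``repeats`` holdout
    errors are computed per candidate d in 1..d_max, and the stopping rule
    is applied to ``n_boot`` bootstrap resamples of the per-d error means:
    with eps_0 := 1, find the first d whose log10 error decrease from d-1
    falls below ``delta`` and keep the preceding dimension (floored at 1);
    if the decrease never flattens the estimate saturates at d_max.  The
    n_boot first-d values are averaged and rounded half away from zero.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = np.asarray(pool, dtype=float)
    if len(X) > n_sample:
        idx = rng.choice(len(X), size=n_sample, replace=False)
        X = X[idx]
    M = X.T                                   # features x windows
    d_max = int(min(d_max, min(M.shape) - 1)) if min(M.shape) > 1 else 1
    d_max = max(d_max, 1)
    cands = np.arange(1, d_max + 1)
    errors = np.empty((repeats, d_max))
    for r in range(repeats):
        errors[r] = cv_error(M, cands, holdout_p=holdout_p, rng=rng)

    # bootstrap the mean error curve, independently per dimensionality
    means = np.empty((n_boot, d_max))
    for j in range(d_max):
        idx = rng.integers(0, repeats, size=(n_boot, repeats))
        means[:, j] = errors[idx, j].mean(axis=1)
    logm = np.log10(np.maximum(means, 1e-300))
    logm = np.hstack([np.zeros((n_boot, 1)), logm])     # eps_0 = 1
    decrease = logm[:, :-1] - logm[:, 1:]               # (n_boot, d_max)
    flat = decrease < delta
    first = np.where(flat.any(axis=1), flat.argmax(axis=1) + 1, d_max + 1)
    d_vals = np.where(first > d_max, d_max, np.maximum(first - 1, 1))
    d_hat = int(np.floor(d_vals.mean() + 0.5))
    if return_info:
        return d_hat, {"errors": errors, "bootstrap_d": d_vals,
                       "d_max": d_max}
    return d_hat


def individual_dimensionality(space: BehaviorSpace, pop_d: int) -> int:
    """Dimensionality used for an individual's space: the population
    estimate, unless fewer components already explain 99% of the
    individual's variance."""
    share = space.variance_share()
    above = np.flatnonzero(share > 0.99)
    m99 = int(above[0]) + 1 if len(above) else len(share)
    return min(int(pop_d), m99)


def reconstruct_window(window: np.ndarray, space: BehaviorSpace,
                       d: int) -> tuple[np.ndarray, np.ndarray]:
    """Project a flattened window onto the top-d modes and reconstruct.

    Returns (reconstruction, scores): mean + V_d V_d^T (window - mean).
    d = 0 reconstructs the mean alone.
    """
    w = np.asarray(window, dtype=float)
    V = space.loadings[:, :d]
    scores = V.T @ (w - space.mean)
    return space.mean + V @ scores, scores
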
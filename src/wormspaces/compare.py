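"""Distances between behavioral spaces and derived analyses.

The core metric is the variance-weighted relative distance between two PCA
spaces: the expected squared residual of a random vector drawn from space V
(loadings v_i, variances lambda_i) after projection onto the span of the
reference space W, normalized to [0, 1] by V's retained variance:

    d(V, W) = sum_i lambda_i |(I - W W^T) v_i|^2 / sum_i lambda_i

Built on it: the symmetrized distance, mean distance as a function of
temporal lag with a bin-shuffle significance test, mode-similarity
matrices, fractional-variance distances in a shared space, complete-linkage
clustering of populations, and t-SNE layouts from precomputed distances.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr

from .spaces import BehaviorSpace

__all__ = [
    "relative_distance",
    "symmetrized_distance",
    "mode_similarity_matrix",
    "pairwise_space_distances",
    "distance_vs_lag",
    "variance_fractions",
    "n_components_70",
    "shared_space_distance",
    "cluster_populations",
    "linkage_to_newick",
    "tsne_embed",
]


def _truncate(space: BehaviorSpace, d: int | None):
    if d is None:
        d = space.d if space.d is not None else space.loadings.shape[1]
    return space.truncated(int(d))


def relative_distance(V: BehaviorSpace | np.ndarray, W: BehaviorSpace | np.ndarray,
                      variances: np.ndarray | None = None,
                      d: int | None = None, r: int | None = None) -> float:
    """Variance-weighted relative distance of space V to reference W, in [0,1].

    ``V``/``W`` may be BehaviorSpace objects (truncated to their estimated
    dimensionality, or to explicit ``d``/``r``) or plain orthonormal basis
    matrices (columns = loadings; then ``variances`` gives V's weights,
    defaulting to equal).
    """
    if isinstance(V, BehaviorSpace):
        Vb, lam = _truncate(V, d)
    else:
        Vb = np.asarray(V, dtype=float)
        lam = (np.ones(Vb.shape[1]) if variances is None
               else np.asarray(variances, dtype=float))
    if isinstance(W, BehaviorSpace):
        Wb, _ = _truncate(W, r)
    else:
        Wb = np.asarray(W, dtype=float)
    total = lam.sum()
    if total <= 0:
        raise ValueError("total variance of V must be positive")
    resid = Vb - Wb @ (Wb.T @ Vb)
    sq = (resid ** 2).sum(axis=0)
    return float(np.clip((lam * sq).sum() / total, 0.0, 1.0))


def symmetrized_distance(V: BehaviorSpace, W: BehaviorSpace,
                         d: int | None = None, r: int | None = None) -> float:
    """(d(V, W) + d(W, V)) / 2, each direction with its own dimensionality."""
    return 0.5 * (relative_distance(V, W, d=d, r=r)
                  + relative_distance(W, V, d=r, r=d))


def mode_similarity_matrix(V: BehaviorSpace | np.ndarray,
                           W: BehaviorSpace | np.ndarray,
                           d: int | None = None, r: int | None = None,
                           ) -> np.ndarray:
    """|v_i . w_j| for each pair of unit-norm modes; entries in [0, 1]."""
    Vb = _truncate(V, d)[0] if isinstance(V, BehaviorSpace) else np.asarray(V)
    Wb = _truncate(W, r)[0] if isinstance(W, BehaviorSpace) else np.asarray(W)
    return np.abs(Vb.T @ Wb)


def pairwise_space_distances(spaces: list[BehaviorSpace | None]) -> np.ndarray:
    """Symmetric matrix of symmetrized distances (NaN for missing spaces)."""
    n = len(spaces)
    D = np.full((n, n), np.nan)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        if spaces[i] is None:
            D[i, i] = np.nan
            continue
        for j in range(i + 1, n):
            if spaces[j] is None:
                continue
            D[i, j] = D[j, i] = symmetrized_distance(spaces[i], spaces[j])
    return D


def _lag_means(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(D)
    lags, means = [], []
    for lag in range(1, n):
        vals = np.array([D[i, i + lag] for i in range(n - lag)])
        vals = vals[np.isfinite(vals)]
        if len(vals):
            lags.append(lag)
            means.append(vals.mean())
    return np.asarray(lags), np.asarray(means)


def distance_vs_lag(spaces_or_distmat, n_shuffle: int = 1000,
                    rng: np.random.Generator | int | None = None) -> dict:
    """Mean space distance per temporal lag, with a bin-shuffle null.

    Accepts a list of per-bin spaces (missing bins as None) or a
    precomputed symmetric distance matrix.  The Pearson correlation of
    mean distance against lag is compared to ``n_shuffle`` random
    orderings of the time bins; the one-sided p-value uses (b+1)/(n+1)
    smoothing so it is never zero.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if isinstance(spaces_or_distmat, np.ndarray):
        D = spaces_or_distmat
    else:
        D = pairwise_space_distances(list(spaces_or_distmat))
    lags, means = _lag_means(D)
    if len(lags) < 3 or np.std(means) == 0:
        return {"lags": lags, "mean_distance": means, "correlation": np.nan,
                "p_value": 1.0, "null": np.array([])}
    obs = pearsonr(lags, means).statistic
    null = np.empty(n_shuffle)
    n = len(D)
    for b in range(n_shuffle):
        perm = rng.permutation(n)
        Dp = D[np.ix_(perm, perm)]
        lp, mp = _lag_means(Dp)
        null[b] = (pearsonr(lp, mp).statistic if len(lp) >= 3
                   and np.std(mp) > 0 else np.nan)
    valid = np.isfinite(null)
    p = (np.sum(null[valid] >= obs) + 1) / (valid.sum() + 1)
    return {"lags": lags, "mean_distance": means, "correlation": float(obs),
            "p_value": float(p), "null": null}


def variance_fractions(windows: np.ndarray, space: BehaviorSpace,
                       n_components: int | None = None) -> np.ndarray:
    """Fraction of a window set's total variance along each of a shared
    space's PCs: f_k = var(score_k) / total variance of the windows."""
    X = np.asarray(windows, dtype=float)
    Xc = X - X.mean(axis=0)
    V = space.loadings if n_components is None else space.loadings[:, :n_components]
    scores = Xc @ V
    total = (Xc ** 2).sum() / (len(X) - 1)
    if total <= 0:
        raise ValueError("zero total variance")
    return scores.var(axis=0, ddof=1) / total


def n_components_70(f_pop: np.ndarray, threshold: float = 0.7) -> int:
    """Smallest n with sum_{k<=n} f_pop_k > threshold (70% rule)."""
    cum = np.cumsum(np.asarray(f_pop, dtype=float))
    above = np.flatnonzero(cum > threshold)
    if not len(above):
        raise ValueError("fractions never exceed the threshold")
    return int(above[0]) + 1


def shared_space_distance(f_ind: np.ndarray, f_pop: np.ndarray,
                          n_b: int) -> float:
    """Fractional-variance distance d = sum_{k<=n_b} |f_ind_k/f_pop_k - 1|."""
    f_ind = np.asarray(f_ind, dtype=float)[:n_b]
    f_pop = np.asarray(f_pop, dtype=float)[:n_b]
    if np.any(f_pop == 0):
        raise ValueError("population variance fraction is zero within n_b")
    return float(np.abs(f_ind / f_pop - 1).sum())


def cluster_populations(distmat: np.ndarray, labels: list[str] | None = None):
    """Complete-linkage merge tree over a symmetric zero-diagonal distance
    matrix.  Returns (scipy linkage matrix, labels)."""
    D = np.asarray(distmat, dtype=float)
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    Z = hierarchy.linkage(squareform(D, checks=False), method="complete")
    if labels is None:
        labels = [str(i) for i in range(len(D))]
    return Z, labels


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage tree as a Newick string with branch
    lengths from merge heights."""
    tree = hierarchy.to_tree(Z)

    def rec(node, parent_height):
        height = 0.0 if node.is_leaf() else node.dist
        length = max(parent_height - height, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        inner = ",".join(rec(ch, height) for ch in (node.left, node.right))
        return f"({inner}):{length:.6g}"

    if tree.is_leaf():
        return f"{labels[tree.id]};"
    inner = ",".join(rec(ch, tree.dist) for ch in (tree.left, tree.right))
    return f"({inner});"


def tsne_embed(distmat: np.ndarray, perplexity: float = 20.0,
               random_state: int = 0) -> np.ndarray:
    """2-D t-SNE layout from a precomputed distance matrix (visualization
    only; seeded but non-contractual)."""
    from sklearn.manifold import TSNE

    D = np.asarray(distmat, dtype=float)
    n = len(D)
    perplexity = min(perplexity, max((n - 1) / 3.0, 1.0))
    ts = TSNE(n_components=2, metric="precomputed", init="random",
              perplexity=perplexity, random_state=random_state)
    return ts.fit_transform(D)
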
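"""Uniqueness ranks and long-term individuality statistics.

Within each experiment and developmental bin, individuals are ranked by the
relative distance of their behavioral space to the population's stereotyped
space (fractional ranks for ties), and ranks are normalized to relative
uniqueness values u = (r - 1/2) / n in (0, 1) -- high u means behaviorally
unique, low u stereotypical; the per-bin mean of u is exactly 1/2.

Long-term consistency is quantified by Pearson correlations of u across
individuals between every pair of bins.  Significance comes from shuffle
nulls in which u values are permuted independently within each experiment
and bin: the median pairwise correlation, its per-stage-pair breakdown
(BH-FDR corrected), and the across-individual variance of mean ranks are
each compared one-sided to 1000 such shuffles.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "fractional_ranks",
    "rank_uniqueness",
    "temporal_correlations",
    "median_offdiag_correlation",
    "mean_rank_profile",
    "mean_rank_variance",
    "shuffle_ranks",
    "shuffle_null",
    "stage_pair_consistency",
]

N_STAGES = 5
BINS_PER_STAGE = 10


def fractional_ranks(values: np.ndarray) -> np.ndarray:
    """Ascending ranks with ties averaged ("1 2.5 2.5 4" ranking)."""
    return rankdata(values, method="average")


def rank_uniqueness(distances: np.ndarray,
                    experiments: np.ndarray | None = None) -> np.ndarray:
    """Normalized fractional uniqueness ranks u = (r - 1/2)/n.

    ``distances`` is individuals x bins; ranking is done within each
    experiment (``experiments`` gives per-individual experiment ids;
    default: one experiment) separately in each bin.  The most and least
    unique individuals get 1 - 1/(2n) and 1/(2n).
    """
    D = np.asarray(distances, dtype=float)
    n, b = D.shape
    if experiments is None:
        experiments = np.zeros(n, dtype=int)
    experiments = np.asarray(experiments)
    U = np.empty_like(D)
    for exp in np.unique(experiments):
        rows = np.flatnonzero(experiments == exp)
        ni = len(rows)
        for k in range(b):
            r = fractional_ranks(D[rows, k])
            U[rows, k] = (r - 0.5) / ni
    return U


def temporal_correlations(U: np.ndarray) -> np.ndarray:
    """Pearson correlation over individuals for every pair of bins."""
    U = np.asarray(U, dtype=float)
    if U.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    C = np.corrcoef(U.T)
    np.fill_diagonal(C, 1.0)
    return C


def median_offdiag_correlation(U: np.ndarray) -> float:
    """Median of the pairwise bin-to-bin rank correlations (i < j)."""
    C = temporal_correlations(U)
    iu = np.triu_indices_from(C, k=1)
    return float(np.median(C[iu]))


def mean_rank_profile(U: np.ndarray) -> np.ndarray:
    """Per-individual mean uniqueness rank across bins (global measure in
    (0, 1); high = consistently unique, low = consistently stereotypical)."""
    return np.asarray(U, dtype=float).mean(axis=1)


def mean_rank_variance(U: np.ndarray) -> float:
    """Variance across individuals of the mean uniqueness rank."""
    return float(np.var(mean_rank_profile(U), ddof=1))


def shuffle_ranks(U: np.ndarray, experiments: np.ndarray | None,
                  rng: np.random.Generator) -> np.ndarray:
    """Permute u values independently within each experiment and bin."""
    U = np.asarray(U, dtype=float)
    n, b = U.shape
    if experiments is None:
        experiments = np.zeros(n, dtype=int)
    out = U.copy()
    for exp in np.unique(experiments):
        rows = np.flatnonzero(experiments == exp)
        for k in range(b):
            out[rows, k] = U[rng.permutation(rows), k]
    return out


_STATISTICS = {
    "median_corr": median_offdiag_correlation,
    "mean_rank_variance": mean_rank_variance,
}


def shuffle_null(U: np.ndarray, statistic="median_corr",
                 experiments: np.ndarray | None = None,
                 n_shuffle: int = 1000,
                 rng: np.random.Generator | int | None = None) -> dict:
    """One-sided shuffle test of a consistency statistic.

    p = (#{null >= observed} + 1) / (n_shuffle + 1).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    fn = _STATISTICS[statistic] if isinstance(statistic, str) else statistic
    obs = fn(U)
    null = np.empty(n_shuffle)
    for b in range(n_shuffle):
        null[b] = fn(shuffle_ranks(U, experiments, rng))
    p = (np.sum(null >= obs) + 1) / (n_shuffle + 1)
    return {"observed": float(obs), "null": null, "p_value": float(p)}


def _stage_of_bins(bins: np.ndarray) -> np.ndarray:
    return (np.asarray(bins) - 1) // BINS_PER_STAGE + 1


def _stage_pair_medians(C: np.ndarray, stages: np.ndarray) -> np.ndarray:
    med = np.full((N_STAGES, N_STAGES), np.nan)
    for s in range(1, N_STAGES + 1):
        for t in range(s, N_STAGES + 1):
            ii = np.flatnonzero(stages == s)
            jj = np.flatnonzero(stages == t)
            vals = [C[i, j] for i in ii for j in jj if i < j]
            if vals:
                med[s - 1, t - 1] = med[t - 1, s - 1] = float(np.median(vals))
    return med


def stage_pair_consistency(U: np.ndarray, bins: np.ndarray,
                           experiments: np.ndarray | None = None,
                           n_shuffle: int = 1000, fdr_alpha: float = 0.05,
                           rng: np.random.Generator | int | None = None,
                           ) -> dict:
    """Median rank correlation within each pair of developmental stages.

    ``bins`` gives the developmental bin index (1..50) of each column of U
    (the consistency range is typically bins 6-50).  For every unique
    stage pair the median correlation over the cell's bin pairs is
    compared to the same shuffled datasets used for the global test; the
    15 one-sided p-values are Benjamini-Hochberg corrected.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    bins = np.asarray(bins)
    stages = _stage_of_bins(bins)
    C = temporal_correlations(U)
    obs = _stage_pair_medians(C, stages)
    null = np.empty((n_shuffle, N_STAGES, N_STAGES))
    for b in range(n_shuffle):
        Cs = temporal_correlations(shuffle_ranks(U, experiments, rng))
        null[b] = _stage_pair_medians(Cs, stages)
    counts = np.sum(null >= obs[None], axis=0)
    pmat = (counts + 1) / (n_shuffle + 1)
    iu = np.triu_indices(N_STAGES)
    cells = [(i, j) for i, j in zip(*iu) if np.isfinite(obs[i, j])]
    pvals = np.array([pmat[i, j] for i, j in cells])
    if len(pvals):
        reject, p_adj, _, _ = multipletests(pvals, alpha=fdr_alpha,
                                            method="fdr_bh")
    else:
        reject, p_adj = np.array([], bool), np.array([])
    sig = np.zeros((N_STAGES, N_STAGES), dtype=bool)
    padj_mat = np.full((N_STAGES, N_STAGES), np.nan)
    for (i, j), rj, pa in zip(cells, reject, p_adj):
        sig[i, j] = sig[j, i] = bool(rj)
        padj_mat[i, j] = padj_mat[j, i] = pa
    return {"median": obs, "p_value": pmat, "p_adjusted": padj_mat,
            "significant": sig}
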
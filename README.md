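# wormspaces

Unsupervised mapping of stereotyped and individual-unique behavioral spaces
from *C. elegans* posture dynamics across development.

Long-term imaging of single worms from hatching to adulthood produces, for
each animal, hundreds of thousands of body postures. `wormspaces` turns such
recordings into a developmental atlas of *behavioral spaces*: per-bin PCA
spaces of posture dynamics whose loading vectors are the dominant movement
modes, compared across time and across individuals with a variance-weighted
subspace metric. It answers two questions: how does the population's
stereotyped repertoire of movement modes progress through development, and
which individuals occupy behavioral spaces of their own — and do they do so
consistently across life stages?

## Pipeline

1. **posture** — each cropped worm image becomes a contour (marching
   squares), two body ends (contour-curvature peaks), a 41-point equally
   spaced midline (averaged head→tail splines of the two contour halves) and
   a vector of k = 37 signed midline turning angles. Frames with multiple
   contours, unreliable end tracking (distance ratio > 0.2), missing-ratio
   runs, or curled shapes (windowed roundness Z > 3) are omitted.
2. **headtail** — time is split into segments of consecutive retained
   frames; within each segment the head is the end with the larger mean log
   ratio of smoothed side-to-side speeds, kept when the confidence |mean
   lsr| exceeds 0.05.
3. **devtime** — lethargus (molting quiescence) episodes are detected from
   block-averaged center-of-mass speed quantiles; their midpoints define the
   stage boundaries used to age-normalize each animal into 50 developmental
   bins (10 per stage). All overlapping 10-s curvature windows are pooled
   per bin.
4. **spaces** — PCA per pool; the significant dimensionality d is estimated
   by bi-cross-validation: hold out random rows and columns of the window
   matrix M = [[A, B], [C, D]], factor D, reconstruct the held-out block A,
   and find where the log₁₀ reconstruction error stops improving
   (bootstrap-averaged).
5. **compare** — the relative distance between spaces (V, λ) and W,

       d(V, W) = Σᵢ λᵢ |(I − W Wᵀ) vᵢ|² / Σᵢ λᵢ ∈ [0, 1],

   its symmetrized form, distance-vs-lag curves with bin-shuffle nulls,
   mode-similarity matrices, shared-space fractional-variance distances,
   complete-linkage clustering and t-SNE layouts.
6. **individuality** — per bin, individuals are ranked by their distance to
   the population (fractional ranks, normalized to u = (r − ½)/n); long-term
   consistency of uniqueness is tested against 1000 within-bin shuffles of
   the ranks, overall and per stage pair (BH-FDR).
7. **synth** — generators with planted ground truth for every stage: worm
   image sequences, drifting low-rank window populations with
   individual-unique modes, and COM traces with lethargus dips.

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
from wormspaces import synth, spaces, compare, individuality as ind

# a small population whose stereotyped space drifts across 10 developmental
# bins, with planted per-individual uniqueness magnitudes
pools, truth = synth.simulate_population(n_bins=10, seed=0)
n = len(pools)

# stereotyped behavioral space of bin 5 and its dimensionality
pool = synth.population_pool(pools, 5)
d_hat = spaces.estimate_dimensionality(pool, d_max=15, n_sample=500,
                                       repeats=5, n_boot=1000, rng=0)
print(f"bin 5: {pool.shape[0]} pooled windows, estimated dimensionality d = {d_hat}")

# relative distance of every individual's space to the population's
dist = np.empty((n, 10))
for j, b in enumerate(range(1, 11)):
    pop = spaces.fit_space(synth.population_pool(pools, b), n_components=15)
    pop.d = d_hat
    for i in range(n):
        isp = spaces.fit_space(pools[i][b])
        isp.d = spaces.individual_dimensionality(isp, d_hat)
        dist[i, j] = compare.relative_distance(isp, pop)

U = ind.rank_uniqueness(dist)
res = ind.shuffle_null(U, "median_corr", n_shuffle=1000, rng=1)
print(f"median rank correlation across bins: {res['observed']:.3f} "
      f"(shuffle p = {res['p_value']:.4f})")
mu = ind.mean_rank_profile(U)
print(f"Spearman(planted uniqueness, mean rank) = "
      f"{spearmanr(truth.eta, mu).statistic:.2f}")
```

Output:

```
bin 5: 1200 pooled windows, estimated dimensionality d = 6
median rank correlation across bins: 0.929 (shuffle p = 0.0010)
Spearman(planted uniqueness, mean rank) = 0.98
```

The estimated dimensionality (6) is the planted population rank (5) plus
one of the strongest planted individual-unique modes present in the pooled
windows. The median correlation of uniqueness ranks across bins (0.93,
shuffle p = 0.001) shows that individuals keep their relative uniqueness as
the space drifts, and the mean uniqueness rank recovers the planted
uniqueness ordering almost perfectly.

A command-line driver wraps the same library:

```sh
wormspaces posture --images frames/ --out worm.h5     # images -> curvature
wormspaces run --out results/ --seed 1 --fast         # synthetic end-to-end
wormspaces simulate --out trace.csv --seed 1          # COM trace generator
```

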
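"""Window- and distance-based comparison methods.

Four conventional clusterings of binding-site patterns used as yardsticks
for the likelihood-based methods:

* window-based K-means / hierarchical clustering — bin the region into w
  equal windows, cluster the per-TF count vectors (Lloyd K-means, or Ward
  agglomeration);
* k-function-based hierarchical clustering — similarity of two TFs is the
  number of cross-TF site pairs within a distance threshold, normalized by
  the product of site counts; average-linkage agglomeration;
* co-localization-vector hierarchical clustering — correlation of binned
  count vectors (bin width = the threshold); distance 1 - r, average
  linkage.

`optimal_grid_search` tunes the window width / threshold by minimizing the
AMCR against the *true* labels over replicates.  That mirrors how such
baselines are conventionally given their best case in simulation
comparisons; it is an evaluation device and not a usable analysis method,
since real data offer no true labels to tune against.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .evaluation import mcr
from .nhpp import GenomicRegion


def window_counts(paths, region: GenomicRegion, w: int) -> np.ndarray:
    """Per-TF counts over w equal-width windows; the last window is closed
    on the right so boundary sites are kept."""
    if w < 2:
        raise ValueError("need at least 2 windows")
    edges = np.linspace(region.lo, region.hi, w + 1)
    return np.array([np.histogram(p.sites, bins=edges)[0] for p in paths])


def window_kmeans(paths, k: int, w: int, region: GenomicRegion, seed=0, n_init=10):
    counts = window_counts(paths, region, w)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(counts) + 1


def window_hclust(paths, k: int, w: int, region: GenomicRegion, method="ward"):
    counts = window_counts(paths, region, w)
    Z = linkage(counts, method=method)
    return fcluster(Z, t=k, criterion="maxclust")


def kfunction_similarity(paths, threshold: float) -> np.ndarray:
    """Normalized count of cross-TF site pairs within the threshold."""
    if threshold <= 0:
        raise ValueError("distance threshold must be positive")
    n = len(paths)
    S = np.zeros((n, n))
    for i in range(n):
        si = paths[i].sites
        for j in range(i + 1, n):
            sj = paths[j].sites
            if si.size == 0 or sj.size == 0:
                continue
            lo = np.searchsorted(sj, si - threshold, side="left")
            hi = np.searchsorted(sj, si + threshold, side="right")
            S[i, j] = S[j, i] = (hi - lo).sum() / (si.size * sj.size)
    return S


def kfunction_hclust(paths, k: int, threshold: float, region=None, method="average"):
    S = kfunction_similarity(paths, threshold)
    iu = np.triu_indices(len(paths), k=1)
    vals = S[iu]
    span = vals.max() - vals.min()
    if span > 0:
        # rescale similarities over the pairs to [0, 1], then distance = 1 - s
        D = 1.0 - (S - vals.min()) / span
    else:
        D = np.zeros_like(S)
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=method)
    return fcluster(Z, t=k, criterion="maxclust")


def colocalization_vectors(paths, region: GenomicRegion, threshold: float) -> np.ndarray:
    """Per-TF binned count vectors with bin width equal to the threshold."""
    if threshold <= 0:
        raise ValueError("bin width must be positive")
    n_bins = max(2, int(np.ceil(region.length / threshold)))
    edges = np.linspace(region.lo, region.hi, n_bins + 1)
    return np.array([np.histogram(p.sites, bins=edges)[0] for p in paths])


def coloc_hclust(paths, k: int, threshold: float, region=None, method="average"):
    vectors = colocalization_vectors(paths, region, threshold).astype(float)
    sd = vectors.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(vectors)
    # TFs with a constant vector have undefined correlation; treat as 0
    R[np.isnan(R)] = 0.0
    R[sd == 0, :] = 0.0
    R[:, sd == 0] = 0.0
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method=method)
    return fcluster(Z, t=k, criterion="maxclust")


def optimal_grid_search(paths_generator, method, grid, T: int, base_seed: int = 0):
    """Tune a baseline's parameter to minimize AMCR over T replicates.

    ``paths_generator(seed) -> (paths, true_labels)``;
    ``method(paths, param, seed) -> labels``.  Returns
    ``(best_param, best_amcr, best_ppc, amcr_by_param)``.  Each replicate's
    dataset is generated once and reused for every grid value, so the curve
    is a paired comparison.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty parameter grid")
    datasets = [paths_generator(base_seed + r) for r in range(T)]
    amcr_by_param = {}
    ppc_by_param = {}
    for param in grid:
        values = [
            mcr(truth, method(paths, param, base_seed + r))
            for r, (paths, truth) in enumerate(datasets)
        ]
        values = np.asarray(values)
        amcr_by_param[param] = float(values.mean())
        ppc_by_param[param] = float(np.mean(values == 0.0))
    best = min(grid, key=lambda p: amcr_by_param[p])
    return best, amcr_by_param[best], ppc_by_param[best], amcr_by_param
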
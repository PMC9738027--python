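"""NHPP-likelihood hierarchical clustering (NLH).

Agglomerative clustering of sample paths under the likelihood linkage

    D(G_i, G_j) = -[ sum_{s in G_j} log pi(s | lambda_i_hat)
                   + sum_{s in G_i} log pi(s | lambda_j_hat) ],

i.e. the symmetrized negative cross log-likelihood between two clusters'
fitted intensities.  The linkage is evaluated on the *refitted* intensities
of the current clusters at every step (no Lance–Williams recurrence exists
for it), may be negative, and need not grow monotonically along the merge
sequence — consumers must not assume an ultrametric.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .estimation import FitConfig, LikelihoodWorkspace, fit_intensity_mle
from .nhpp import GenomicRegion, SamplePath, log_likelihood


@dataclass(frozen=True)
class Dendrogram:
    """Full merge history of an NLH run.

    ``merges`` follows the scipy linkage-matrix convention: row m merges
    nodes ``(id_a, id_b)`` (leaves are 0..n-1, the node created by row m is
    n+m) at raw linkage ``height`` with resulting ``size`` leaves.
    ``display_heights`` are the raw heights affinely mapped onto [1, 10] for
    plotting; the map is monotone so the merge order is preserved.
    """

    merges: np.ndarray
    labels: tuple
    display_heights: np.ndarray | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def raw_heights(self) -> np.ndarray:
        return self.merges[:, 2]


def likelihood_linkage(cluster_a, cluster_b, region, config: FitConfig | None = None):
    """Symmetrized negative cross log-likelihood between two path clusters."""
    cluster_a, cluster_b = list(cluster_a), list(cluster_b)
    if not cluster_a or not cluster_b:
        raise ValueError("likelihood linkage requires two non-empty clusters")
    config = config or FitConfig()
    lam_a = fit_intensity_mle(cluster_a, region, config).intensity
    lam_b = fit_intensity_mle(cluster_b, region, config).intensity
    cross = sum(log_likelihood(p, lam_a) for p in cluster_b)
    cross += sum(log_likelihood(p, lam_b) for p in cluster_a)
    return -float(cross)


class _LinkageEngine:
    """Caches per-cluster fits and per-path event-term designs.

    A cluster's fitted intensity depends only on its own members, so fits
    are computed once per cluster creation and reused for every pairwise
    linkage involving that cluster.
    """

    def __init__(self, paths, region, config: FitConfig):
        self.paths = list(paths)
        self.region = region
        self.config = config
        self.workspace = LikelihoodWorkspace(region, config)
        all_sites = np.concatenate([p.sites for p in self.paths]) if self.paths else np.empty(0)
        self.site_matrix = self.workspace.site_design(all_sites)
        counts = np.array([p.n for p in self.paths])
        self.offsets = np.concatenate([[0], np.cumsum(counts)])

    def fit(self, member_indices):
        members = [self.paths[i] for i in member_indices]
        result = fit_intensity_mle(
            members, self.region, self.config, workspace=self.workspace
        )
        c = result.intensity.coefficients
        integral = self.workspace.integral(c)
        if self.site_matrix.shape[0]:
            logs = np.log(np.maximum(self.site_matrix @ c, self.workspace.floor))
            per_path = np.add.reduceat(logs, self.offsets[:-1])
            per_path[self.offsets[:-1] == self.offsets[1:]] = 0.0
        else:
            per_path = np.zeros(len(self.paths))
        # log-likelihood of every path under this cluster's intensity
        return result.intensity, per_path - integral

    def linkage(self, fit_a, members_a, fit_b, members_b) -> float:
        _, ll_a = fit_a
        _, ll_b = fit_b
        return -float(ll_a[members_b].sum() + ll_b[members_a].sum())


def nlh_cluster(
    paths, region: GenomicRegion, config: FitConfig | None = None
) -> Dendrogram:
    """Agglomerate sample paths bottom-up under the likelihood linkage.

    Starts from singletons and repeatedly merges the pair of current
    clusters with the minimum linkage, refitting the merged cluster's
    intensity before the next round.  Exact linkage ties are broken toward
    the lexicographically lowest pair of cluster creation indices, which
    makes the dendrogram deterministic.
    """
    paths = list(paths)
    n = len(paths)
    if n < 2:
        raise ValueError("hierarchical clustering needs at least 2 paths")
    config = config or FitConfig()
    engine = _LinkageEngine(paths, region, config)

    members = {i: np.array([i]) for i in range(n)}
    fits = {i: engine.fit(members[i]) for i in range(n)}
    cache: dict[tuple, float] = {}
    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        active = sorted(members)
        best = None
        for ia, a in enumerate(active):
            for b in active[ia + 1 :]:
                key = (a, b)
                if key not in cache:
                    cache[key] = engine.linkage(fits[a], members[a], fits[b], members[b])
                d = cache[key]
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        merged = np.concatenate([members[a], members[b]])
        merges[step] = (a, b, d, merged.size)
        for cid in (a, b):
            del members[cid], fits[cid]
        cache = {k: v for k, v in cache.items() if a not in k and b not in k}
        members[next_id] = merged
        fits[next_id] = engine.fit(merged)
        next_id += 1
    labels = tuple(p.label or f"path{i}" for i, p in enumerate(paths))
    return scale_branch_lengths(Dendrogram(merges, labels))


def scale_branch_lengths(dendrogram: Dendrogram) -> Dendrogram:
    """Attach display heights: raw heights affinely mapped onto [1, 10]."""
    h = dendrogram.raw_heights
    span = h.max() - h.min()
    if span == 0:
        display = np.ones_like(h)
    else:
        display = 1.0 + 9.0 * (h - h.min()) / span
    return replace(dendrogram, display_heights=display)


def cut_dendrogram(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Flat clustering with k clusters: stop the merge sequence after n-k
    merges.  Labels are 1..k, numbered by first appearance in path order.

    Because the likelihood linkage is not monotone, cutting by merge count
    (not by a height threshold) is the well-defined operation.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}")
    parent = {i: i for i in range(n)}
    groups = {i: [i] for i in range(n)}
    next_id = n
    for step in range(n - k):
        a, b = int(dendrogram.merges[step, 0]), int(dendrogram.merges[step, 1])
        groups[next_id] = groups.pop(a) + groups.pop(b)
        next_id += 1
    labels = np.zeros(n, dtype=int)
    for gid, leaves in groups.items():
        labels[np.array(leaves)] = min(leaves)
    out = np.zeros(n, dtype=int)
    for new, rep in enumerate(dict.fromkeys(labels.tolist()), start=1):
        out[labels == rep] = new
    return out


def cut_at_height(dendrogram: Dendrogram, height: float, use_display=True) -> np.ndarray:
    """Flat clustering from all merges with height <= the threshold."""
    h = dendrogram.display_heights if use_display else dendrogram.raw_heights
    if h is None:
        raise ValueError("dendrogram has no display heights; scale first")
    n = dendrogram.n_leaves
    groups = {i: [i] for i in range(n)}
    next_id = n
    for step in range(n - 1):
        if h[step] > height:
            next_id += 1
            continue
        a, b = int(dendrogram.merges[step, 0]), int(dendrogram.merges[step, 1])
        if a in groups and b in groups:
            groups[next_id] = groups.pop(a) + groups.pop(b)
        next_id += 1
    labels = np.zeros(n, dtype=int)
    for new, (gid, leaves) in enumerate(sorted(groups.items()), start=1):
        labels[np.array(leaves)] = new
    return labels


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick serialization; each child edge carries the display height of
    the merge that created its parent (the scaled between-cluster distance)."""
    dendro = (
        dendrogram
        if dendrogram.display_heights is not None
        else scale_branch_lengths(dendrogram)
    )
    n = dendro.n_leaves

    def node(idx: int) -> str:
        if idx < n:
            return dendro.labels[idx].replace(" ", "_")
        step = idx - n
        a, b = int(dendro.merges[step, 0]), int(dendro.merges[step, 1])
        d = dendro.display_heights[step]
        return f"({node(a)}:{d:.6g},{node(b)}:{d:.6g})"

    return node(2 * n - 2) + ";"


def write_linkage_table(dendrogram: Dendrogram, path) -> None:
    """Tab-separated merge table: step, node_a, node_b, raw height, size."""
    with open(path, "w") as fh:
        fh.write("step\tnode_a\tnode_b\traw_height\tsize\n")
        for step, (a, b, h, size) in enumerate(dendrogram.merges):
            fh.write(f"{step}\t{int(a)}\t{int(b)}\t{h:.17g}\t{int(size)}\n")
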
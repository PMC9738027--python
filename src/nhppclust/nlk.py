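"""NHPP-likelihood K-means (NLK): partitional clustering of sample paths.

Lloyd-type alternation where the per-cluster intensity function plays the
role of the centroid and the (negative) NHPP log-likelihood replaces
Euclidean distance.  The optimized criterion is

    max_G  sum_{i=1..k} sum_{s_j in G_i} log pi(s_j | lambda_i_hat),

with lambda_i_hat the joint MLE of cluster i's paths.  With a normal
likelihood on scalar data the same alternation reduces to classical
K-means; the generic engine `likelihood_kmeans` makes that substitution
possible and is what the NHPP front end wraps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .estimation import FitConfig, LikelihoodWorkspace, fit_intensity_mle
from .nhpp import GenomicRegion, IntensityFunction, SamplePath, log_likelihood

_MONOTONE_SLACK = 1e-6


@dataclass(frozen=True)
class NLKConfig:
    fit: FitConfig = field(default_factory=FitConfig)
    n_init: int = 10
    max_iter: int = 100
    tol: float = 1e-6
    rng_seed: int = 0
    #: random restarts for centroid refits inside the iteration; the moment
    #: start plus the incumbent centroid already give the refit a warm start
    #: and a monotonicity guarantee, so 0 is a sound fast default
    inner_restarts: int = 0
    #: looser optimizer tolerance for inner refits (final quality is set by
    #: the convergence of the outer alternation, not by each inner polish)
    inner_tolerance: float = 1e-4


@dataclass
class Partition:
    """NLK output: assignments in 1..k, fitted per-cluster intensities."""

    assignments: np.ndarray
    intensities: list
    objective: float
    n_iterations: int
    converged: bool = True
    objective_history: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.intensities)


def likelihood_kmeans(
    n_items: int,
    k: int,
    fit_fn,
    loglik_fn,
    *,
    n_init: int = 10,
    max_iter: int = 100,
    tol: float = 1e-6,
    rng=None,
    initial_assignments=None,
):
    """Generic likelihood K-means over abstract items.

    ``fit_fn(member_indices, incumbent_model) -> model`` refits a cluster
    model; including ``incumbent_model`` as a candidate must guarantee the
    refit never has lower total likelihood on the members.
    ``loglik_fn(models) -> (n_items, k) array`` evaluates every item under
    every model.  Returns ``(assignments0, models, objective, n_iter,
    history)`` with 0-based assignments, best over ``n_init`` runs.
    """
    if k < 1 or k > n_items:
        raise ValueError(f"k must be in 1..{n_items}, got {k}")
    rng = np.random.default_rng(rng)

    if initial_assignments is None:
        inits = []
        for _ in range(n_init):
            while True:
                a = rng.integers(0, k, n_items)
                if np.unique(a).size == k:
                    break
            inits.append(a)
    else:
        inits = [np.asarray(a, dtype=int) for a in initial_assignments]
        for a in inits:
            if np.unique(a).size != k:
                raise ValueError("initial assignment must use all k clusters")

    best = None
    for init in inits:
        result = _single_run(init, k, fit_fn, loglik_fn, max_iter, tol)
        if best is None or result[2] > best[2]:
            best = result
    return best


def _single_run(assign, k, fit_fn, loglik_fn, max_iter, tol):
    assign = assign.copy()
    models = [fit_fn(np.flatnonzero(assign == i), None) for i in range(k)]
    L = loglik_fn(models)
    objective = float(L[np.arange(assign.size), assign].sum())
    history = [objective]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new_assign = np.argmax(L, axis=1)  # argmax ties -> lowest index
        moved_from = {}
        # empty-cluster repair: donate the worst-fitting path from a
        # multi-member cluster (lowest log-likelihood under its own centroid)
        for empty in range(k):
            if np.any(new_assign == empty):
                continue
            sizes = np.bincount(new_assign, minlength=k)
            candidates = np.flatnonzero(sizes[new_assign] > 1)
            own = L[candidates, new_assign[candidates]]
            donor = candidates[np.argmin(own)]
            moved_from[empty] = models[new_assign[donor]]
            new_assign[donor] = empty
        changed = new_assign != assign
        if not np.any(changed):
            break
        new_models = list(models)
        for i in range(k):
            members = np.flatnonzero(new_assign == i)
            if np.any(new_assign[changed] == i) or np.any(assign[changed] == i):
                incumbent = moved_from.get(i, models[i])
                new_models[i] = fit_fn(members, incumbent)
        L = loglik_fn(new_models)
        new_objective = float(L[np.arange(assign.size), new_assign].sum())
        if not new_objective >= objective - _MONOTONE_SLACK * max(1.0, abs(objective)):
            raise AssertionError(
                f"likelihood K-means objective decreased: {objective} -> {new_objective}"
            )
        assign, models = new_assign, new_models
        gain = new_objective - objective
        objective = new_objective
        history.append(objective)
        if gain < tol:
            break
    return assign, models, objective, n_iter, history


class _NHPPClusterProblem:
    """Caches site design matrices so loglik of all paths under all centroids
    is a single matrix product per iteration."""

    def __init__(self, paths, region, fit_config: FitConfig, inner_restarts: int,
                 inner_tolerance: float):
        self.paths = list(paths)
        self.region = region
        self.fit_config = fit_config
        self.inner_config = replace(
            fit_config,
            n_restarts=inner_restarts,
            optimizer_tolerance=max(fit_config.optimizer_tolerance, inner_tolerance),
            xatol=max(fit_config.xatol, 1e-3),
        )
        self.workspace = LikelihoodWorkspace(region, fit_config)
        all_sites = (
            np.concatenate([p.sites for p in self.paths])
            if self.paths
            else np.empty(0)
        )
        self.site_matrix = self.workspace.site_design(all_sites)
        counts = np.array([p.n for p in self.paths])
        self.path_slices = np.concatenate([[0], np.cumsum(counts)])
        self._first = True

    def fit(self, member_indices, incumbent_model):
        members = [self.paths[i] for i in member_indices]
        incumbent = incumbent_model.intensity if incumbent_model is not None else None
        config = self.fit_config if self._first else self.inner_config
        return fit_intensity_mle(
            members, self.region, config, incumbent=incumbent, workspace=self.workspace
        )

    def loglik_matrix(self, models):
        self._first = False
        coefs = np.column_stack([m.intensity.coefficients for m in models])
        integrals = np.array([self.workspace.integral(c) for c in coefs.T])
        if self.site_matrix.shape[0]:
            lam = np.maximum(self.site_matrix @ coefs, self.workspace.floor)
            logs = np.log(lam)
            event_terms = np.add.reduceat(logs, self.path_slices[:-1], axis=0)
            event_terms[self.path_slices[:-1] == self.path_slices[1:]] = 0.0
        else:
            event_terms = np.zeros((len(self.paths), coefs.shape[1]))
        return event_terms - integrals[None, :]


def nlk_cluster(
    paths,
    k: int,
    config: NLKConfig | None = None,
    region: GenomicRegion | None = None,
    initial_assignments=None,
) -> Partition:
    """Run NLK clustering and return the best partition over random inits.

    Initialization assigns paths uniformly at random to k clusters
    (re-drawn if a cluster comes up empty); iteration alternates
    re-assignment to the highest-likelihood centroid with per-cluster
    intensity refits until the assignment repeats, the objective gain falls
    below ``tol``, or ``max_iter`` is hit.
    """
    paths = list(paths)
    config = config or NLKConfig()
    if region is None:
        raise ValueError("region is required")
    problem = _NHPPClusterProblem(
        paths, region, config.fit, config.inner_restarts, config.inner_tolerance
    )
    assign0, models, objective, n_iter, history = likelihood_kmeans(
        len(paths),
        k,
        problem.fit,
        problem.loglik_matrix,
        n_init=config.n_init,
        max_iter=config.max_iter,
        tol=config.tol,
        rng=config.rng_seed,
        initial_assignments=initial_assignments,
    )
    return Partition(
        assignments=assign0 + 1,
        intensities=[m.intensity for m in models],
        objective=objective,
        n_iterations=n_iter,
        converged=n_iter < config.max_iter,
        objective_history=history,
    )


def nlk_objective(paths, partition: Partition) -> float:
    """Recompute the NLK criterion from assignments and intensities."""
    total = 0.0
    k = partition.k
    for path, a in zip(paths, partition.assignments):
        if not 1 <= a <= k:
            raise ValueError(f"cluster index {a} out of range 1..{k}")
        total += log_likelihood(path, partition.intensities[a - 1])
    return total


def assign_step(paths, intensities) -> np.ndarray:
    """Assign each path to the highest-likelihood intensity (1-based).

    Exact likelihood ties go to the lowest cluster index.
    """
    L = np.array(
        [[log_likelihood(p, lam) for lam in intensities] for p in paths]
    )
    return np.argmax(L, axis=1) + 1


def objective_vs_k(paths, region, ks, config: NLKConfig | None = None):
    """Objective curve over candidate k, for elbow-style model selection."""
    config = config or NLKConfig()
    return [
        (k, nlk_cluster(paths, k, config, region=region).objective) for k in ks
    ]
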
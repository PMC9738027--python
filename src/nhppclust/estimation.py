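"""Maximum-likelihood estimation of NHPP intensities by basis-coefficient search.

Given sample paths ``s_1 .. s_n`` assumed to share one intensity, the joint
log-likelihood is ``-n int_D lambda + sum_i sum_j log lambda(s_ij)``, and the
estimate is the coefficient vector maximizing it.  The search is a
derivative-free (Nelder–Mead) multi-start local optimization: the clamped
expansion makes the likelihood non-concave, so we start from several random
perturbations of a moment-matched start and keep the best local optimum.

For the orthonormal cosine basis the moment-matched start is the unbiased
empirical coefficient estimator ``c_i = (1/n) sum_events psi_i(s)``, which
satisfies ``E[c_i] = int psi_i lambda = c_i`` exactly; in practice it lands
very close to the MLE and the local search only polishes it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import minimize

from .nhpp import (
    FLOOR_DEFAULT,
    QUAD_POINTS,
    GenomicRegion,
    IntensityFunction,
    SamplePath,
    basis_design,
    joint_log_likelihood,
)


@dataclass(frozen=True)
class FitConfig:
    """Settings for intensity estimation.

    n_coefficients is the truncation length K of the basis expansion; the
    sparse-representation assumption is expressed by choosing K, not by an
    automatic support-selection step.
    """

    basis_kind: str = "cosine_dct"
    n_coefficients: int = 8
    n_restarts: int = 5
    optimizer_tolerance: float = 1e-6
    rng_seed: int = 0
    coefficient_bound_factor: float = 10.0
    max_fev: int | None = None
    #: simplex step tolerance; looser values trade a little likelihood for speed
    xatol: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_coefficients < 1:
            raise ValueError("n_coefficients must be >= 1")
        if self.n_restarts < 0:
            raise ValueError("n_restarts must be >= 0")
        if self.optimizer_tolerance <= 0:
            raise ValueError("optimizer_tolerance must be > 0")


@dataclass(frozen=True)
class FitResult:
    intensity: IntensityFunction
    log_likelihood: float
    converged: bool


def _simpson_weights(grid: np.ndarray) -> np.ndarray:
    # composite-Simpson weights on a uniform odd-length grid
    h = grid[1] - grid[0]
    w = np.full(grid.size, 2.0)
    w[1::2] = 4.0
    w[0] = w[-1] = 1.0
    return w * h / 3.0


class LikelihoodWorkspace:
    """Precomputed design matrices for fast repeated likelihood evaluation.

    Shared by the fitter and by the clustering algorithms, which need the
    log-likelihood of every path under every candidate intensity many times.
    """

    def __init__(self, region: GenomicRegion, config: FitConfig):
        self.region = region
        self.config = config
        self.grid = np.linspace(region.lo, region.hi, QUAD_POINTS)
        self.weights = _simpson_weights(self.grid)
        self.grid_design = basis_design(
            config.basis_kind, config.n_coefficients, self.grid, region
        )
        self._sqrt_T = np.sqrt(region.length)
        self.floor = FLOOR_DEFAULT

    def site_design(self, sites: np.ndarray) -> np.ndarray:
        return basis_design(
            self.config.basis_kind, self.config.n_coefficients, sites, self.region
        )

    def integral(self, coefficients: np.ndarray) -> float:
        """``int_D max(sum c_i psi_i, floor)`` with the same rule as `cumulative`."""
        values = self.grid_design @ coefficients
        if self.config.basis_kind == "constant":
            return float(max(coefficients[0], self.floor) * self.region.length)
        if self.config.basis_kind == "cosine_dct" and values.min() >= self.floor:
            return float(coefficients[0] * self._sqrt_T)
        return float(self.weights @ np.maximum(values, self.floor))

    def intensity(self, coefficients: np.ndarray) -> IntensityFunction:
        return IntensityFunction(
            np.asarray(coefficients, dtype=float),
            self.config.basis_kind,
            self.region,
            floor=self.floor,
        )


def _negative_joint_loglik(c, workspace, site_matrix, n_paths, bound):
    if np.any(np.abs(c) > bound):
        return np.inf
    value = n_paths * workspace.integral(c)
    if site_matrix.shape[0]:
        lam = site_matrix @ c
        value -= float(np.sum(np.log(np.maximum(lam, workspace.floor))))
    return value


def _moment_start(workspace, site_matrix, n_paths, total_sites):
    cfg = workspace.config
    if cfg.basis_kind == "cosine_dct":
        # unbiased empirical coefficients: E[sum_events psi_i(s)] = c_i
        return site_matrix.sum(axis=0) / n_paths
    # constant / bspline: flat start at the average event rate
    rate = total_sites / (n_paths * workspace.region.length)
    if cfg.basis_kind == "bspline":
        # clamped B-splines form a partition of unity, so equal coefficients
        # give a flat intensity at that rate
        return np.full(cfg.n_coefficients, rate)
    return np.array([rate])


def fit_intensity_mle(
    paths,
    region: GenomicRegion,
    config: FitConfig | None = None,
    incumbent: IntensityFunction | None = None,
    workspace: LikelihoodWorkspace | None = None,
) -> FitResult:
    """Joint MLE of one intensity from one or more sample paths.

    ``incumbent`` optionally supplies a known-good coefficient vector (e.g.
    the previous centroid during clustering); it is both an extra start and a
    lower bound on the returned likelihood, which makes iterative refitting
    monotone.  With the constant basis the closed form
    ``lambda = total_sites / (n_paths * |D|)`` is returned exactly.
    """
    paths = list(paths)
    if not paths:
        raise ValueError("need at least one sample path")
    config = config or FitConfig()
    workspace = workspace or LikelihoodWorkspace(region, config)
    n_paths = len(paths)
    all_sites = np.concatenate([p.sites for p in paths]) if paths else np.empty(0)
    total = all_sites.size

    if total == 0:
        # degenerate input: no events anywhere -> floor-level constant rate
        coef = np.zeros(config.n_coefficients)
        intensity = workspace.intensity(coef)
        return FitResult(intensity, joint_log_likelihood(paths, intensity), converged=False)

    if config.basis_kind == "constant":
        rate = total / (n_paths * region.length)
        intensity = workspace.intensity(np.array([rate]))
        return FitResult(intensity, joint_log_likelihood(paths, intensity), converged=True)

    site_matrix = workspace.site_design(all_sites)
    mean_rate = total / (n_paths * region.length)
    bound = config.coefficient_bound_factor * max(
        1.0, mean_rate * np.sqrt(region.length)
    )

    rng = np.random.default_rng(config.rng_seed)
    starts = [np.clip(_moment_start(workspace, site_matrix, n_paths, total), -bound, bound)]
    scale = 0.25 * max(1.0, float(np.linalg.norm(starts[0])) / np.sqrt(config.n_coefficients))
    for _ in range(config.n_restarts):
        starts.append(
            np.clip(starts[0] + rng.normal(0.0, scale, config.n_coefficients), -bound, bound)
        )

    args = (workspace, site_matrix, n_paths, bound)
    best_c, best_f, best_ok = None, np.inf, False
    for start in starts:
        res = minimize(
            _negative_joint_loglik,
            start,
            args=args,
            method="Nelder-Mead",
            options={
                "fatol": config.optimizer_tolerance,
                "xatol": config.xatol,
                "maxfev": config.max_fev or 400 * config.n_coefficients,
            },
        )
        if res.fun < best_f:
            best_c, best_f, best_ok = res.x, res.fun, bool(res.success)
    # the incumbent guards against the local search ending worse than the
    # current centroid, which keeps iterative refitting monotone
    if incumbent is not None and incumbent.n_coefficients == config.n_coefficients:
        f_inc = _negative_joint_loglik(np.asarray(incumbent.coefficients), *args)
        if f_inc < best_f:
            best_c, best_f, best_ok = np.asarray(incumbent.coefficients), f_inc, True
    intensity = workspace.intensity(best_c)
    return FitResult(intensity, -best_f, converged=best_ok)


def l2_distance(
    intensity_a: IntensityFunction, intensity_b: IntensityFunction, region=None
) -> float:
    """``sqrt(int_D (lambda_a - lambda_b)^2 dt)``.

    For two cosine expansions on the same region this is the Euclidean
    distance between (zero-padded) coefficient vectors, by orthonormality of
    the basis (clamping ignored, i.e. the raw expansions are compared);
    otherwise the clamped intensities are compared by Simpson quadrature.
    """
    if intensity_a.region != intensity_b.region:
        raise ValueError("intensities live on different regions")
    region = intensity_a.region
    if intensity_a.basis_kind == "cosine_dct" and intensity_b.basis_kind == "cosine_dct":
        K = max(intensity_a.n_coefficients, intensity_b.n_coefficients)
        ca = np.zeros(K)
        cb = np.zeros(K)
        ca[: intensity_a.n_coefficients] = intensity_a.coefficients
        cb[: intensity_b.n_coefficients] = intensity_b.coefficients
        return float(np.linalg.norm(ca - cb))
    grid = np.linspace(region.lo, region.hi, QUAD_POINTS)
    diff = intensity_a(grid) - intensity_b(grid)
    return float(np.sqrt(simpson(diff**2, x=grid)))


def export_coefficients(intensities, path) -> None:
    """Plain-text coefficient table: basis_kind, K, c_0..c_{K-1} per row."""
    if isinstance(intensities, IntensityFunction):
        intensities = [intensities]
    with open(path, "w") as fh:
        for lam in intensities:
            coefs = "\t".join(format(c, ".17g") for c in lam.coefficients)
            fh.write(f"{lam.basis_kind}\t{lam.n_coefficients}\t{coefs}\n")
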
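"""Nonhomogeneous Poisson process (NHPP) model objects.

A transcription factor's binding sites on a genomic region ``D = [lo, hi]``
are treated as one sample path of an NHPP with intensity function
``lambda(t) >= 0``.  Counts on any interval ``[a, b]`` are then Poisson with
mean ``m(a, b) = int_a^b lambda(s) ds``, and the log-likelihood of observing
sites ``s_1 <= ... <= s_m`` is (up to an additive constant that is dropped
consistently everywhere in this package)

    log pi(s | lambda) = -int_D lambda(s) ds + sum_j log lambda(s_j).

Intensities are represented by coefficients on one of three basis families:

``cosine_dct``
    The orthonormal cosine family on ``[lo, hi]`` of length ``T``:
    ``psi_0 = 1/sqrt(T)`` and ``psi_i(t) = sqrt(2/T) cos(i pi (t-lo)/T)``.
``bspline``
    A clamped B-spline basis (default degree 6, 10 uniform interior knots).
``constant``
    The single function ``psi_0(t) = 1``, so the coefficient *is* the rate.

Because a finite cosine expansion can dip below zero, evaluated intensities
are clamped at a small positive floor both when simulating and inside the
log terms of the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.integrate import simpson
from scipy.interpolate import BSpline

FLOOR_DEFAULT = 1e-8
#: number of points of the fixed composite-Simpson quadrature grid (odd)
QUAD_POINTS = 2001
#: grid used to bound the intensity for thinning, and safety inflation
ENVELOPE_POINTS = 10_001
ENVELOPE_SAFETY = 1.0001

BASIS_KINDS = ("cosine_dct", "bspline", "constant")

DEFAULT_BSPLINE_DEGREE = 6
DEFAULT_BSPLINE_INTERIOR_KNOTS = 10


@dataclass(frozen=True)
class GenomicRegion:
    """A bounded study region ``[lo, hi]`` on the (scaled) genome axis."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"region requires lo < hi, got [{self.lo}, {self.hi}]")

    @property
    def length(self) -> float:
        return self.hi - self.lo

    def contains(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (t >= self.lo) & (t <= self.hi)


@dataclass(frozen=True)
class SamplePath:
    """One TF's ordered binding-site coordinates (an NHPP realization)."""

    sites: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        sites = np.sort(np.asarray(self.sites, dtype=float).ravel())
        object.__setattr__(self, "sites", sites)

    @property
    def n(self) -> int:
        return self.sites.size


def _bspline_knots(region: GenomicRegion, degree: int, n_interior: int) -> np.ndarray:
    interior = np.linspace(region.lo, region.hi, n_interior + 2)[1:-1]
    return np.concatenate(
        [np.full(degree + 1, region.lo), interior, np.full(degree + 1, region.hi)]
    )


def basis_design(
    basis_kind: str,
    n_coefficients: int,
    t,
    region: GenomicRegion,
    degree: int = DEFAULT_BSPLINE_DEGREE,
    n_interior_knots: int = DEFAULT_BSPLINE_INTERIOR_KNOTS,
) -> np.ndarray:
    """Design matrix ``Psi[j, i] = psi_i(t_j)`` for the first K basis functions."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    K = n_coefficients
    if K < 1:
        raise ValueError("need at least one basis function")
    T = region.length
    if basis_kind == "cosine_dct":
        i = np.arange(K)
        design = np.cos(np.outer(t - region.lo, i) * (np.pi / T)) * np.sqrt(2.0 / T)
        design[:, 0] = 1.0 / np.sqrt(T)
        return design
    if basis_kind == "constant":
        if K != 1:
            raise ValueError("constant basis has a single function")
        return np.ones((t.size, 1))
    if basis_kind == "bspline":
        n_basis = n_interior_knots + degree + 1
        if K != n_basis:
            raise ValueError(
                f"bspline basis with degree {degree} and {n_interior_knots} interior "
                f"knots has {n_basis} functions, got K={K}"
            )
        knots = _bspline_knots(region, degree, n_interior_knots)
        tt = np.clip(t, region.lo, region.hi)
        return BSpline.design_matrix(tt, knots, degree).toarray()
    raise ValueError(f"unknown basis_kind {basis_kind!r}; expected one of {BASIS_KINDS}")


def basis_eval(basis_kind, index, t, region, **kwargs):
    """Evaluate the ``index``-th basis function at ``t``."""
    if index < 0:
        raise ValueError("basis index must be >= 0")
    if basis_kind == "bspline":
        n_basis = kwargs.get("n_interior_knots", DEFAULT_BSPLINE_INTERIOR_KNOTS) + kwargs.get(
            "degree", DEFAULT_BSPLINE_DEGREE
        ) + 1
        design = basis_design(basis_kind, n_basis, t, region, **kwargs)
    else:
        design = basis_design(basis_kind, index + 1, t, region, **kwargs)
    values = design[:, index]
    return values[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else values


@dataclass(frozen=True)
class IntensityFunction:
    """A nonnegative rate function on a region, held as basis coefficients.

    Evaluation clamps the raw expansion at ``floor`` so the function is
    strictly positive everywhere (required inside the likelihood's log terms
    and by the thinning simulator).
    """

    coefficients: np.ndarray
    basis_kind: str
    region: GenomicRegion
    floor: float = FLOOR_DEFAULT
    degree: int = DEFAULT_BSPLINE_DEGREE
    n_interior_knots: int = DEFAULT_BSPLINE_INTERIOR_KNOTS

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float).ravel()
        if c.size < 1:
            raise ValueError("need at least one coefficient")
        if self.basis_kind not in BASIS_KINDS:
            raise ValueError(f"unknown basis_kind {self.basis_kind!r}")
        object.__setattr__(self, "coefficients", c)

    @property
    def n_coefficients(self) -> int:
        return self.coefficients.size

    def _design(self, t) -> np.ndarray:
        return basis_design(
            self.basis_kind,
            self.n_coefficients,
            t,
            self.region,
            degree=self.degree,
            n_interior_knots=self.n_interior_knots,
        )

    def raw(self, t) -> np.ndarray:
        """Unclamped basis expansion ``sum_i c_i psi_i(t)``."""
        values = self._design(t) @ self.coefficients
        return values[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else values

    def __call__(self, t):
        return np.maximum(self.raw(t), self.floor)

    @cached_property
    def _quad_grid(self) -> np.ndarray:
        return np.linspace(self.region.lo, self.region.hi, QUAD_POINTS)

    @cached_property
    def _quad_values(self) -> np.ndarray:
        return np.atleast_1d(self.raw(self._quad_grid))

    def max_value(self, n_points: int = ENVELOPE_POINTS) -> float:
        grid = np.linspace(self.region.lo, self.region.hi, n_points)
        return float(np.max(np.maximum(np.atleast_1d(self.raw(grid)), self.floor)))


def intensity_at(intensity: IntensityFunction, t):
    """Clamped intensity value; ``t`` must lie inside the region."""
    if not np.all(intensity.region.contains(t)):
        raise ValueError("coordinate outside the intensity's region")
    return intensity(t)


def _cosine_closed_form_integral(intensity: IntensityFunction, a: float, b: float) -> float:
    """Integral of the raw cosine expansion on [a, b] (no clamping)."""
    region = intensity.region
    T = region.length
    c = intensity.coefficients
    total = c[0] * (b - a) / np.sqrt(T)
    if c.size > 1:
        i = np.arange(1, c.size)
        scale = np.sqrt(2.0 / T) * T / (i * np.pi)
        total += np.sum(
            c[1:]
            * scale
            * (np.sin(i * np.pi * (b - region.lo) / T) - np.sin(i * np.pi * (a - region.lo) / T))
        )
    return float(total)


def cumulative(intensity: IntensityFunction, a: float, b: float) -> float:
    """Expected event count ``int_a^b max(lambda(s), floor) ds``.

    Closed form is used for the constant basis and for cosine expansions
    that stay above the floor on the quadrature grid; otherwise a fixed
    composite-Simpson rule on the clamped values.
    """
    region = intensity.region
    if a > b:
        raise ValueError(f"need a <= b, got a={a}, b={b}")
    if a < region.lo - 1e-12 or b > region.hi + 1e-12:
        raise ValueError("integration limits outside region")
    if a == b:
        return 0.0
    if intensity.basis_kind == "constant":
        return float(max(intensity.coefficients[0], intensity.floor) * (b - a))
    full = a == region.lo and b == region.hi
    if full:
        grid, values = intensity._quad_grid, intensity._quad_values
    else:
        grid = np.linspace(a, b, QUAD_POINTS)
        values = np.atleast_1d(intensity.raw(grid))
    if intensity.basis_kind == "cosine_dct" and values.min() >= intensity.floor:
        return _cosine_closed_form_integral(intensity, a, b)
    return float(simpson(np.maximum(values, intensity.floor), x=grid))


def log_likelihood(
    path: SamplePath, intensity: IntensityFunction, region: GenomicRegion | None = None
) -> float:
    """NHPP log-likelihood of one sample path (proportionality constant dropped)."""
    region = region or intensity.region
    if path.n and not np.all(region.contains(path.sites)):
        raise ValueError(f"path {path.label!r} has sites outside the region")
    value = -cumulative(intensity, region.lo, region.hi)
    if path.n:
        value += float(np.sum(np.log(intensity(path.sites))))
    return value


def joint_log_likelihood(
    paths, intensity: IntensityFunction, region: GenomicRegion | None = None
) -> float:
    """Sum of per-path log-likelihoods; the integral enters once per path."""
    return float(sum(log_likelihood(p, intensity, region) for p in paths))


def simulate_nhpp(
    intensity: IntensityFunction,
    region: GenomicRegion | None = None,
    rng=None,
    label: str = "",
) -> SamplePath:
    """Draw one NHPP sample path by Lewis–Shedler thinning.

    Homogeneous candidates are generated at rate ``lambda_max`` (the grid
    maximum of the clamped intensity, inflated by a small safety factor) and
    retained with probability ``lambda(t)/lambda_max``.  Exact for bounded
    intensities; event locations are not discretized.
    """
    region = region or intensity.region
    rng = np.random.default_rng(rng)
    lam_max = intensity.max_value() * ENVELOPE_SAFETY
    if lam_max <= 0:
        return SamplePath(np.empty(0), label=label)
    n_candidates = rng.poisson(lam_max * region.length)
    candidates = rng.uniform(region.lo, region.hi, n_candidates)
    u = rng.uniform(0.0, lam_max, n_candidates)
    kept = candidates[u < intensity(candidates)]
    return SamplePath(np.sort(kept), label=label)


def constant_intensity(
    rate: float, region: GenomicRegion, floor: float = FLOOR_DEFAULT
) -> IntensityFunction:
    """Homogeneous Poisson intensity ``lambda(t) = rate``."""
    return IntensityFunction(np.array([rate]), "constant", region, floor=floor)
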
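"""Synthetic-data generators: the four simulation scenarios.

All scenarios live on the region [0, 10].  Scenarios 1, 2, and 4 use fixed
cosine-expansion intensities; Scenario 3 draws random B-spline intensities
per dataset.  Each TF's sample path is an independent NHPP draw from its
cluster's intensity, so the generated data carry exactly the model the
clustering methods assume — real binding data differ (finite peak widths,
inter-TF dependence), which is why these generators measure algorithmic
recovery, not biological validity.

Scenario overview (region [0, 10], k = number of clusters):

* S1 — "easy": n=30, k=3, sizes (10, 9, 11);
  lambda_m(t) = 3 cos((m+1) pi t / 10) + 3 for m = 1, 2, 3.
* S2 — "moderate": n=30, k=3, sizes (15, 10, 5); two-frequency cosine
  combinations, each affinely rescaled to range [0, 6].
* S3 — "hard": n=100, k=10, random sizes; random degree-6 B-spline
  intensities rescaled to [0, 6].
* S4 — hierarchy demo: n=10, k=3, sizes (3, 3, 4);
  lambda_1 = 5 cos(2 pi t/10) + 5,
  lambda_2 = (5/2) cos(2 pi t/10) + (15/4) cos(4 pi t/10) + 15/4,
  lambda_3 = -5 cos(2 pi t/10) + 5,
  so lambda_1 and lambda_3 are vertical mirror images (L2 distance
  sqrt(500)) and lambda_2 sits much closer to lambda_1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nhpp import (
    DEFAULT_BSPLINE_DEGREE,
    DEFAULT_BSPLINE_INTERIOR_KNOTS,
    GenomicRegion,
    IntensityFunction,
    SamplePath,
    simulate_nhpp,
)

REGION = GenomicRegion(0.0, 10.0)

_RESCALE_GRID = 10_001


@dataclass(frozen=True)
class ScenarioSpec:
    scenario_id: str
    n_tfs: int
    k_clusters: int
    cluster_sizes: tuple | str  # fixed composition, or "random"
    description: str


SCENARIOS = {
    "S1": ScenarioSpec("S1", 30, 3, (10, 9, 11), "balanced, 1-frequency cosine"),
    "S2": ScenarioSpec("S2", 30, 3, (15, 10, 5), "unbalanced, 2-frequency cosine, range [0,6]"),
    "S3": ScenarioSpec("S3", 100, 10, "random", "random sizes, degree-6 B-spline, range [0,6]"),
    "S4": ScenarioSpec("S4", 10, 3, (3, 3, 4), "hierarchical trio for NLH"),
}


def cosine_intensity(constant: float, terms: dict, region: GenomicRegion = REGION):
    """Build ``constant + sum_f amp_f cos(f pi t / T)`` as an orthonormal
    cosine expansion (``terms`` maps frequency index f >= 1 to amplitude)."""
    T = region.length
    K = max(terms, default=0) + 1
    c = np.zeros(max(K, 1))
    c[0] = constant * np.sqrt(T)
    for f, amp in terms.items():
        c[f] = amp / np.sqrt(2.0 / T)
    return IntensityFunction(c, "cosine_dct", region)


def _rescale_to_range(intensity: IntensityFunction, lo: float, hi: float):
    """Affine map of an intensity so its grid min/max become (lo, hi).

    Exact in coefficient space: for the cosine basis the constant offset
    goes into c_0; for clamped B-splines (a partition of unity) it is added
    to every coefficient.
    """
    grid = np.linspace(intensity.region.lo, intensity.region.hi, _RESCALE_GRID)
    values = intensity.raw(grid)
    vmin, vmax = float(values.min()), float(values.max())
    if vmax == vmin:
        raise ValueError("cannot rescale a constant intensity to a range")
    a = (hi - lo) / (vmax - vmin)
    b = lo - a * vmin
    c = a * intensity.coefficients.copy()
    if intensity.basis_kind == "cosine_dct":
        c[0] += b * np.sqrt(intensity.region.length)
    elif intensity.basis_kind == "bspline":
        c += b
    else:
        c[0] += b
    return IntensityFunction(
        c,
        intensity.basis_kind,
        intensity.region,
        floor=intensity.floor,
        degree=intensity.degree,
        n_interior_knots=intensity.n_interior_knots,
    )


def _s3_intensity(rng: np.random.Generator) -> IntensityFunction:
    degree = DEFAULT_BSPLINE_DEGREE
    n_interior = DEFAULT_BSPLINE_INTERIOR_KNOTS
    K = n_interior + degree + 1
    raw = IntensityFunction(rng.uniform(0.0, 1.0, K), "bspline", REGION)
    return _rescale_to_range(raw, 0.0, 6.0)


def scenario_intensities(scenario_id: str, rng=None):
    """The per-cluster intensity functions of one scenario.

    S3's intensities are random, so a generator (or seed) is required there;
    the other scenarios are deterministic.
    """
    if scenario_id == "S1":
        return [cosine_intensity(3.0, {f: 3.0}) for f in (2, 3, 4)]
    if scenario_id == "S2":
        raw = [
            cosine_intensity(0.0, {2: 2.0, 3: -1.0}),
            cosine_intensity(0.0, {3: 2.0, 4: 1.0}),
            cosine_intensity(0.0, {2: 1.0, 4: -2.0}),
        ]
        return [_rescale_to_range(lam, 0.0, 6.0) for lam in raw]
    if scenario_id == "S4":
        return [
            cosine_intensity(5.0, {2: 5.0}),
            cosine_intensity(15.0 / 4.0, {2: 5.0 / 2.0, 4: 15.0 / 4.0}),
            cosine_intensity(5.0, {2: -5.0}),
        ]
    if scenario_id == "S3":
        if rng is None:
            raise ValueError("Scenario 3 intensities are random; pass rng or a seed")
        rng = np.random.default_rng(rng)
        return [_s3_intensity(rng) for _ in range(SCENARIOS["S3"].k_clusters)]
    raise ValueError(f"unknown scenario {scenario_id!r}; expected one of {sorted(SCENARIOS)}")


def _random_composition(rng, total: int, parts: int, minimum: int) -> np.ndarray:
    """Uniform composition of ``total`` into ``parts`` parts, each >= minimum
    (stars-and-bars: uniform over weak compositions of the excess)."""
    excess = total - parts * minimum
    if excess < 0:
        raise ValueError("total too small for the minimum part size")
    # positions of parts-1 bars among excess + parts - 1 slots
    bars = np.sort(rng.choice(excess + parts - 1, size=parts - 1, replace=False))
    cuts = np.concatenate([[-1], bars, [excess + parts - 1]])
    return np.diff(cuts) - 1 + minimum


def generate_scenario(scenario_id: str, rng_seed=None):
    """Simulate one dataset: a list of sample paths plus true cluster labels.

    Reproducible given the seed; S3 additionally draws its cluster sizes
    (uniform composition of 100 into 10 parts, each >= 3) and intensities
    from the same generator.
    """
    spec = SCENARIOS.get(scenario_id)
    if spec is None:
        raise ValueError(f"unknown scenario {scenario_id!r}")
    rng = np.random.default_rng(rng_seed)
    if spec.cluster_sizes == "random":
        sizes = _random_composition(rng, spec.n_tfs, spec.k_clusters, 3)
        intensities = scenario_intensities(scenario_id, rng)
    else:
        sizes = np.asarray(spec.cluster_sizes)
        intensities = scenario_intensities(scenario_id)
    paths, labels = [], []
    tf = 0
    for cluster, (size, lam) in enumerate(zip(sizes, intensities), start=1):
        for _ in range(size):
            tf += 1
            path = simulate_nhpp(lam, REGION, rng, label=f"TF{tf:03d}")
            paths.append(path)
            labels.append(cluster)
    return paths, np.asarray(labels)
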
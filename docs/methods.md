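# Methods

## Model

Each transcription factor's binding sites on a bounded study region
`D = [lo, hi]` are modeled as one realization (sample path) of a
nonhomogeneous Poisson process with intensity `λ(t) ≥ 0`. The assumptions
this encodes: binding events in disjoint intervals are independent; two
events never coincide; and the local binding propensity varies along the
region and is fully captured by `λ`. Counts on `[a, b]` are then Poisson
with mean `m(a,b) = ∫_a^b λ(s) ds`, and the log-likelihood of sites
`s_1 … s_m` is, after dropping a data-independent constant,

    ℓ(s | λ) = −∫_D λ(s) ds + Σ_j log λ(s_j).

The constant is dropped *consistently everywhere* (estimation, K-means
objective, hierarchical linkage), so it cancels from every comparison the
package makes. TFs in one cluster are assumed to share one intensity, and
paths are independent across TFs, so a cluster's joint log-likelihood is
the sum of per-path terms with the integral counted once per path.

## Intensity representation and estimation

Intensities are finite basis expansions `λ(t) ≈ Σ_{i<K} c_i ψ_i(t)` with
three families:

* `cosine_dct` — the orthonormal cosine family on `[lo, hi]` of length `T`:
  `ψ_0 = 1/√T`, `ψ_i(t) = √(2/T) cos(iπ(t−lo)/T)`. Default for analysis.
* `bspline` — clamped B-splines (degree 6, 10 uniform interior knots);
  used by the Scenario-3 generator.
* `constant` — `ψ_0 ≡ 1`, so the coefficient is the rate; its MLE is the
  closed form `n / |D|` and is returned exactly.

A finite cosine expansion can go negative, while the likelihood needs
`λ > 0` at observed sites; evaluated intensities are therefore clamped at a
floor of 1e-8, both in the simulator and inside the log terms. The
truncation length K expresses the sparse-representation assumption
directly: it is a configuration choice, not an automatic selection. K
defaults to 8 for data of unknown origin; for the built-in scenarios K=5
(the DC term plus frequencies up to 4) spans every scenario intensity
exactly.

`fit_intensity_mle` maximizes the joint log-likelihood over coefficients by
multi-start Nelder–Mead (derivative-free: the clamp makes the objective
non-concave and only piecewise smooth). Starts are a moment-matched point
plus random perturbations of it. For the orthonormal cosine basis the
moment start is the empirical coefficient estimator
`ĉ_i = (1/n) Σ_events ψ_i(s)`, which is unbiased
(`E[Σ_events ψ_i(s)] = ∫ ψ_i λ = c_i`) and in practice lands so close to
the MLE that the local search only polishes it. Coefficients are confined
to a box of 10× the empirical rate scale to prevent divergence into
clamped regions. Integrals use the closed form when the expansion stays
above the floor on the quadrature grid, otherwise composite Simpson on a
fixed 2001-point grid; the same rule is used everywhere so reported
likelihoods are internally consistent to float precision.

During clustering, centroid refits are warm-started from the incumbent
centroid and the moment start, with no extra random restarts and a looser
simplex tolerance (1e-4 on the log-likelihood). The incumbent is always
kept as a fallback candidate, which makes each refit at least as good as
the previous centroid — this is what guarantees the K-means objective never
decreases. Tightening these tolerances or adding restarts was checked not
to change clustering accuracy on the built-in scenarios; it only slows the
loop.

## NLK — likelihood K-means

Lloyd alternation with intensities as centroids: random uniform initial
assignment (re-drawn if a cluster comes up empty), then repeat
(re-assign each path to the centroid giving it the highest log-likelihood,
ties to the lowest cluster index; repair empty clusters by donating the
worst-fitting path from a multi-member cluster; refit each changed
cluster's intensity) until the assignment repeats, the objective gain drops
below 1e-6, or 100 iterations. The best of `n_init = 10` seeded
initializations is returned. The objective is asserted non-decreasing
within every run. With a normal likelihood on scalar data the same engine
reproduces classical K-means, which the test suite checks against
scikit-learn's Lloyd implementation.

Model selection for k is deliberately manual: `objective_vs_k` reports the
objective curve for elbow-style inspection rather than choosing k
automatically.

## NLH — likelihood-linkage hierarchical clustering

Agglomeration from singletons under
`D(G_i, G_j) = −[Σ_{s∈G_j} ℓ(s|λ̂_i) + Σ_{s∈G_i} ℓ(s|λ̂_j)]`,
the symmetrized negative cross log-likelihood of each cluster's paths under
the other cluster's fitted intensity. The linkage is defined on clusters,
not by a pairwise-update recurrence, so after every merge the merged
cluster's intensity is refitted and its linkages recomputed; linkages
between untouched clusters are cached (their fits cannot change). Exact
ties are broken toward the lexicographically smallest pair of cluster
creation indices, making the dendrogram deterministic.

The linkage can be negative (well-matched clusters with many events) and is
not monotone along the merge sequence; the implementation never assumes an
ultrametric, and flat clusterings are taken by merge count, not height.
Display heights are the raw heights affinely mapped onto [1, 10] (all-equal
heights map to 1), a monotone map used for the Newick export and plotting.

**Known limitation.** Because cross log-likelihood scales with event
counts, the linkage discriminates by intensity *shape* at comparable total
mass, not by rate alone: for homogeneous clusters that differ only in rate,
a formed high-count clade produces large positive cross terms and absorbs
lower-rate paths, so rate-only hierarchies are not recovered. The
hierarchy-demo scenario (three intensities of comparable mass and distinct
shape) is the regime the method is designed for; the test suite's
"well-separated groups" property accordingly uses disjoint-support groups
with comparable counts.

## Simulation

`simulate_nhpp` uses Lewis–Shedler thinning: homogeneous candidates at rate
`λ_max` (the clamped maximum over a 10,001-point grid, inflated by 1.0001
as a safety factor against grid undersampling), each kept with probability
`λ(t)/λ_max`. Exact for bounded intensities; event locations are never
discretized. All randomness flows through one `numpy` Generator per call.

## Scenarios

All scenarios live on `[0, 10]` (a hypothetical, pre-scaled genomic
region). S1: 30 TFs, 3 clusters of 10/9/11, single-frequency cosine
intensities `3cos(fπt/10)+3`, f = 2, 3, 4 (each integrates to 30 expected
sites per path). S2: 30 TFs, clusters of 15/10/5, two-frequency cosine
combinations affinely rescaled so each ranges over [0, 6] (grid min/max on
10,001 points; exact in coefficient space). S3: 100 TFs, 10 clusters with
sizes drawn uniformly from compositions of 100 into 10 parts ≥ 3
(stars-and-bars sampling), intensities as random degree-6 B-splines with
uniform(0,1) coefficients rescaled to [0, 6]. S4 (hierarchy demo): 10 TFs,
clusters of 3/3/4 with intensities `5cos(2πt/10)+5`,
`(5/2)cos(2πt/10)+(15/4)cos(4πt/10)+15/4`, `−5cos(2πt/10)+5`; the first
and third are vertical mirror images (L2 distance √500 ≈ 22.36) and the
middle one is much closer to the first (10.83 vs 19.16).

What the generators emulate: independent point patterns drawn exactly from
the model the clustering assumes, with cluster structure purely in the
intensity functions. What they do not emulate: finite peak widths,
inter-TF dependence, copy-number and mappability artifacts, or intensity
variation across genomic loci. Passing the simulation studies therefore
demonstrates algorithmic recovery under the model, not biological validity
on real ChIP-seq data.

A note on the S4 linkage ordering: the raw formula of the middle intensity
is negative on (2.50, 3.04) and (6.96, 7.50), where it is clamped to the
floor. The third cluster has substantial mass there, so with
`log(floor) ≈ −18.4` the expected linkage between clusters 2 and 3 exceeds
that between 1 and 3, even though their L2 order is reversed. The
substantive hierarchy — clusters 1 and 2 are by far the closest pair and
merge first — is unaffected and is what the tests assert.

## Evaluation

Partitions are compared label-invariantly through adjacency (co-membership)
matrices: `mcr` is the fraction of disagreeing upper-triangular entries,
AMCR its mean over replicates, PPC the fraction of replicates with mcr
exactly 0. Replicate r of an experiment uses seed `base_seed + r` for both
data generation and clustering initialization, so a whole experiment is
reproducible from one integer.

Baselines: window-based K-means (scikit-learn Lloyd, 10 inits) and
hierarchical clustering (Ward) on per-window count vectors; k-function
hierarchical clustering on cross-pair counts within a distance threshold
(normalized by the product of site counts, similarities rescaled to [0, 1]
across pairs, average linkage); co-localization-vector hierarchical
clustering on 1 − Pearson r of binned counts (bin width = the threshold,
zero-variance vectors get r = 0, average linkage). The linkage choices are
conventional defaults and are configurable. `optimal_grid_search` tunes the
window width or threshold by minimizing AMCR against the *true* labels —
an evaluation device that gives the baselines their best case; it is not a
usable analysis method, because real data provide no truth to tune
against.

Problem sizes used by the packaged experiments: 150 seeded replicates for
the Scenario 1/2 NLK studies and 100 for the window-grid search in
`scripts/acceptance.py`; 100 replicates in the corresponding tests; 100
datasets for the hierarchy recovery check; 20 for the ten-cluster
Scenario 3 exercise. The original studies used 1000 replicates; the
statistics being averages and proportions, the scaled-down versions carry
proportionally wider Monte-Carlo error, which the test tolerances reflect.

## ChIP-seq preprocessing

Site intervals (BED, 0-based half-open) are reduced to midpoints;
midpoints falling in the strand-oriented `[−8000, +2000]` window around a
gene's TSS (1-based input, converted internally) become per-gene offsets.
Genes with at least `min_tfs` distinct bound TFs (default 8) are retained.
One path per TF is then built either by *pooling* (all gene windows
overlaid on [0, 10]; assumes one binding intensity shared across genes) or
by *concatenating* (gene windows laid end to end in lexicographic gene-id
order, then scaled to [0, 10]; drops that assumption at the cost of a
composite region). Both conserve per-TF site counts. Summary tables report
per-TF counts and six-number summaries with type-7 (linear interpolation)
quartiles. Midpoint-vs-summit site reduction and the gene order are fixed
conventions, exposed as parameters.

## Design choices made where the design was open

* Thinning (not inversion) for simulation: exact and simple for bounded
  intensities.
* Floor 1e-8 for clamping, applied identically in simulation, estimation
  and likelihood evaluation.
* Nelder–Mead with moment-matched start for the MLE; K exposed as
  configuration instead of sparse-support selection.
* Empty-cluster repair (donate the worst-fitting path) rather than
  dropping to k−1 clusters.
* Refit-after-merge for the hierarchical linkage (the linkage is defined on
  clusters; no Lance–Williams shortcut exists for it).
* Deterministic tie-breaking everywhere (lowest index / lexicographic pair).
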
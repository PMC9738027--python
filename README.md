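# nhppclust

Clustering transcription-factor (TF) binding-site patterns with
nonhomogeneous Poisson process (NHPP) likelihoods.

ChIP-seq experiments yield, for each TF, a set of binding-site locations on
the genome. TFs that co-regulate genes tend to bind with similar positional
patterns, so grouping TFs by the *shape* of their binding-site distribution
is a way to discover candidate regulatory modules. Classical clustering
wants fixed-length vectors; binding-site lists are point patterns of
varying length. This package treats each TF's sites on a study region
`D = [lo, hi]` as one sample path of an NHPP with intensity `λ(t)` and
clusters the paths directly through the likelihood

```
log π(s | λ) = −∫_D λ(t) dt + Σ_j log λ(s_j)          (up to a constant)
```

Two algorithms are provided:

* **NLK** (NHPP-likelihood K-means) — Lloyd-type alternation in which the
  per-cluster intensity function is the centroid and assignment maximizes
  `Σ_i Σ_{s_j ∈ G_i} log π(s_j | λ̂_i)`;
* **NLH** (NHPP-likelihood hierarchical clustering) — agglomeration under
  the likelihood linkage
  `D(G_i, G_j) = −[Σ_{s∈G_j} log π(s|λ̂_i) + Σ_{s∈G_i} log π(s|λ̂_j)]`,
  with Newick/dendrogram output.

Cluster intensities are estimated by maximum likelihood over coefficients
of an orthonormal cosine (DCT-type) expansion,
`λ(t) ≈ Σ_i c_i ψ_i(t)`, clamped at a small positive floor.

Also included: an exact thinning simulator and four synthetic study
scenarios; label-invariant evaluation (misclassification rate via adjacency
matrices, AMCR, PPC); four conventional baselines (window-based K-means and
hierarchical clustering, k-function and co-localization-vector hierarchical
clustering, with oracle grid search of their tuning parameter); and a
ChIP-seq preprocessing front end that turns per-TF BED files plus a TSS
table into clustering-ready sample paths by pooling or concatenating
strand-oriented [−8 kb, +2 kb] promoter windows.

## Worked example

```python
import numpy as np
from nhppclust import (REGION, generate_scenario, nlk_cluster, NLKConfig,
                       FitConfig, mcr)

paths, truth = generate_scenario("S1", rng_seed=7)   # 30 TFs, 3 clusters
cfg = NLKConfig(fit=FitConfig(n_coefficients=5, rng_seed=7), n_init=10,
                rng_seed=7)
part = nlk_cluster(paths, k=3, config=cfg, region=REGION)
print("objective:", round(part.objective, 2))
print("mcr vs truth:", mcr(truth, part.assignments))
```

prints

```
objective: 346.98
mcr vs truth: 0.0
```

The objective is the summed NHPP log-likelihood of every path under its
cluster's fitted intensity (larger is better; the absolute value depends on
the dropped likelihood constant, only comparisons are meaningful). An `mcr`
of 0.0 means the recovered partition agrees with the simulated truth on
every one of the C(30,2) co-membership pairs.

The same from the shell:

```sh
nhppclust simulate --scenario S1 --seed 7 --out paths.tsv
nhppclust nlk --input paths.tsv --k 3 -K 5 --seed 7 --out clusters.tsv
nhppclust nlh --input paths.tsv -K 5 --newick-out tree.nwk
```

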
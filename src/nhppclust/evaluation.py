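"""Label-invariant evaluation of clusterings over replicated simulations.

Cluster labels from unsupervised runs are arbitrary, so partitions are
compared through their co-membership (adjacency) matrices: entry (i, j) is 1
iff items i and j share a cluster.  The misclassification rate of one
replicate is the fraction of disagreeing upper-triangular entries between
the true and predicted adjacency matrices; AMCR averages it over replicates
and PPC counts the replicates in which it is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scenarios import REGION, generate_scenario


def adjacency(labels) -> np.ndarray:
    """Symmetric binary co-membership matrix with zero diagonal."""
    labels = np.asarray(labels)
    A = (labels[:, None] == labels[None, :]).astype(np.int8)
    np.fill_diagonal(A, 0)
    return A


def mcr(true_labels, predicted_labels) -> float:
    """Fraction of item pairs on which the two partitions disagree.

    Invariant to relabeling of either argument and symmetric in them.
    """
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("labelings have different lengths")
    n = true_labels.size
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, k=1)
    same_true = true_labels[:, None] == true_labels[None, :]
    same_pred = predicted_labels[:, None] == predicted_labels[None, :]
    return float(np.mean(same_true[iu] != same_pred[iu]))


@dataclass(frozen=True)
class EvalSummary:
    amcr: float
    ppc: float
    T: int
    mcr_values: tuple

    def __str__(self) -> str:
        return f"AMCR={self.amcr:.4f}  PPC={100 * self.ppc:.1f}%  (T={self.T})"


def evaluate_replicates(scenario_id: str, method, T: int, base_seed: int = 0) -> EvalSummary:
    """AMCR/PPC of a clustering method over T simulated replicates.

    ``method(paths, region, seed) -> labels``.  Replicate r uses seed
    ``base_seed + r`` both for data generation and for the method, so the
    whole experiment is reproducible from one integer.
    """
    if T < 1:
        raise ValueError("need at least one replicate")
    values = []
    for r in range(T):
        seed = base_seed + r
        paths, truth = generate_scenario(scenario_id, seed)
        predicted = method(paths, REGION, seed)
        values.append(mcr(truth, predicted))
    values = np.asarray(values)
    return EvalSummary(
        amcr=float(values.mean()),
        ppc=float(np.mean(values == 0.0)),
        T=T,
        mcr_values=tuple(values),
    )


def nlk_method(k: int, make_config):
    """Adapter: wrap NLK as an `evaluate_replicates` method.

    ``make_config(seed)`` builds the NLKConfig for one replicate so the
    clustering initialization follows the replicate seed.
    """
    from .nlk import nlk_cluster

    def method(paths, region, seed):
        return nlk_cluster(paths, k, make_config(seed), region=region).assignments

    return method
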
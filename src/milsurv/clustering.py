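"""Per-patient k-means phenotype clustering (Model 1 input units).

Each patient's instances are clustered independently of every other
patient's — phenotypes are patient-level, never cohort-level. Super-patch
instances are flattened (g*g*d) before clustering. When a bag holds fewer
instances than k, the effective number of clusters is the bag size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .encoding import PatientBag

__all__ = ["PhenotypeSet", "cluster_bag", "assignments_to_frame"]

DEFAULT_K = 10  # best average test c-index in the k in {4,6,8,10,12} sweep


@dataclass(frozen=True)
class PhenotypeSet:
    """Partition of one patient's bag into phenotype clusters.

    ``cluster_stacks[c]`` is the (x_c, p) stack of instance vectors in
    cluster c; sum_c x_c equals the bag size. Empty clusters are absent, so
    the number of stacks C may be smaller than the requested k.
    """

    patient_id: str
    k: int
    assignment: np.ndarray  # per instance, cluster id in [0, k)
    cluster_stacks: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if sum(s.shape[0] for s in self.cluster_stacks) != self.assignment.size:
            raise ValueError("cluster stacks do not partition the bag")
        if self.assignment.size and self.assignment.max() >= self.k:
            raise ValueError("cluster id out of range")

    @property
    def n_phenotypes(self) -> int:
        return len(self.cluster_stacks)

    @property
    def inertia(self) -> float:
        return sum(float(((s - s.mean(axis=0)) ** 2).sum()) for s in self.cluster_stacks)


def cluster_bag(bag: PatientBag, k: int = DEFAULT_K, seed: int = 0) -> PhenotypeSet:
    """k-means phenotypes of one bag (10 restarts, k-means++ seeding).

    Deterministic given ``seed``. With k = 1 all instances share one
    cluster; with bag size <= k, each instance can form its own cluster.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = bag.feature_matrix()
    n = X.shape[0]
    eff_k = min(k, n)
    if eff_k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=eff_k, n_init=10, random_state=int(seed) % (2**32))
        labels = km.fit_predict(X)
    stacks = tuple(X[labels == c] for c in np.unique(labels))
    return PhenotypeSet(patient_id=bag.patient_id, k=k, assignment=labels, cluster_stacks=stacks)


def assignments_to_frame(phenos: list[PhenotypeSet]) -> pd.DataFrame:
    """Long-format `patient_id,instance_index,cluster` table."""
    rows = [
        {"patient_id": p.patient_id, "instance_index": i, "cluster": int(c)}
        for p in phenos
        for i, c in enumerate(p.assignment)
    ]
    return pd.DataFrame(rows, columns=["patient_id", "instance_index", "cluster"])
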
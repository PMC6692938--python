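"""Unsupervised structure over signature CpGs: hierarchical clustering, PCA,
and projection of a signature onto external cohorts.

Sample distance is either 1 - Pearson correlation between methylation
profiles (the two-way heatmap convention) or the Euclidean norm; trees are
agglomerative and cut into k groups. PCA scores use a fixed sign convention
(the largest-magnitude loading of each component is positive) so projections
are reproducible run to run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .diffmeth import Signature
from .io import BetaMatrix

METRICS = ("pearson", "euclidean")
LINKAGES = ("average", "complete", "ward")


@dataclass
class ClusterAssignment:
    labels: pd.Series          # sample_id -> 1..k
    linkage_matrix: np.ndarray
    metric: str
    linkage: str
    k: int
    probe_linkage: np.ndarray | None = None  # two-way: probe tree, if requested


def _sample_distances(values: np.ndarray, metric: str,
                      sample_ids: list[str]) -> np.ndarray:
    if metric == "pearson":
        sd = values.std(axis=1)
        if np.any(sd == 0):
            bad = sample_ids[int(np.argmax(sd == 0))]
            raise ValueError(
                f"sample {bad!r} has a constant profile; Pearson distance undefined")
        return pdist(values, metric="correlation")
    return pdist(values, metric="euclidean")


def hierarchical_cluster(matrix: BetaMatrix, metric: str = "pearson",
                         linkage: str = "average", k: int = 3,
                         cluster_probes: bool = False) -> ClusterAssignment:
    """Agglomerative clustering of samples on a signature-restricted matrix."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")
    n = matrix.shape[1]
    if n < 2:
        raise ValueError("need >= 2 samples")
    if k > n:
        raise ValueError("k cannot exceed the number of samples")
    profiles = matrix.values.to_numpy(dtype=float).T  # samples x probes
    dist = _sample_distances(profiles, metric, matrix.sample_ids)
    Z = hierarchy.linkage(dist, method=linkage)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=matrix.sample_ids, name="cluster")
    probe_Z = None
    if cluster_probes:
        pv = matrix.values.to_numpy(dtype=float)
        pdist_probes = _sample_distances(pv, metric, matrix.probe_ids) \
            if metric == "pearson" else pdist(pv, metric="euclidean")
        probe_Z = hierarchy.linkage(pdist_probes, method=linkage)
    return ClusterAssignment(labels, Z, metric, linkage, k, probe_Z)


def pca_project(matrix: BetaMatrix, n_components: int = 3
                ) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample component scores and explained-variance fractions."""
    X = matrix.values.to_numpy(dtype=float).T  # samples x probes
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 samples")
    n_components = min(n_components, n - 1, X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    # sign convention: largest-magnitude loading of each component positive
    for j in range(n_components):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[j] = -load
            scores[:, j] = -scores[:, j]
    cols = [f"PC{j+1}" for j in range(n_components)]
    return (pd.DataFrame(scores, index=matrix.sample_ids, columns=cols),
            pca.explained_variance_ratio_.copy())


def project_external(external: BetaMatrix, signature: Signature
                     ) -> tuple[BetaMatrix, float]:
    """Restrict an external cohort to the signature probes present in both.

    Returns the restricted matrix and the coverage fraction (signature
    probes found / signature size); downstream clustering runs unchanged.
    """
    wanted = signature.probe_ids
    present = [p for p in wanted if p in external.values.index]
    if not present:
        raise ValueError("no signature probes present in the external matrix")
    coverage = len(present) / len(wanted)
    return external.restrict_probes(present), coverage
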
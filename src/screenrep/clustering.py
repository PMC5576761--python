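"""Study clustering from configuration-space correlations.

For each pair of studies the joint non-null prior probability is estimated
by a two-study configuration EM; together with the per-study marginal
non-null probabilities this yields a phi coefficient between the studies'
latent non-null indicators.  Averaging over bootstrap resamples of the
genes gives a robust correlation matrix, which is thresholded into an
unweighted graph and partitioned by map-equation (infomap) community
detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .config_em import em_unrestricted
from .models import StudyMatrix, TwoGroupsModel

__all__ = [
    "StudyCorrelation",
    "ClusterPartition",
    "pairwise_joint_prior",
    "study_correlation",
    "bootstrap_correlation",
    "estimate_correlations",
    "cluster_studies",
]

_PAIR_CONFIGS = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.int8)


@dataclass
class StudyCorrelation:
    """Marginal/joint non-null probabilities and the phi-correlation matrix."""

    a_marginal: np.ndarray  # (m,)
    a_joint: np.ndarray  # (m, m), diagonal = a_marginal
    r: np.ndarray  # (m, m), diagonal = 1

    def __post_init__(self):
        self.a_marginal = np.asarray(self.a_marginal, dtype=float)
        self.a_joint = np.asarray(self.a_joint, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        if not np.allclose(self.r, self.r.T):
            raise ValueError("correlation matrix must be symmetric")
        if np.any(np.abs(self.r) > 1.0 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")


@dataclass
class ClusterPartition:
    """A partition of the m studies into disjoint, covering clusters."""

    clusters: list
    m: int

    def __post_init__(self):
        self.clusters = [sorted(int(i) for i in c) for c in self.clusters]
        seen = [i for c in self.clusters for i in c]
        if any(len(c) == 0 for c in self.clusters):
            raise ValueError("clusters must be non-empty")
        if sorted(seen) != list(range(self.m)):
            raise ValueError("clusters must disjointly cover all studies")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> np.ndarray:
        lab = np.empty(self.m, dtype=int)
        for ci, members in enumerate(self.clusters):
            lab[members] = ci
        return lab


def pairwise_joint_prior(
    z_i,
    z_j,
    model_i: TwoGroupsModel,
    model_j: TwoGroupsModel,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> float:
    """P(both studies non-null) from a two-study configuration EM.

    Runs the unrestricted EM over the four pairwise configurations and
    returns the estimated probability of (1, 1).  The EM uses the unshrunk
    non-null densities so that the learned marginals stay consistent with
    each model's pi0 (power shrinkage is a posterior-side correction, not
    part of the mixture the priors are fitted to).  If the EM degenerates
    the independence product of the marginal non-null probabilities is
    returned with a warning.
    """
    Z = np.column_stack([np.asarray(z_i, float), np.asarray(z_j, float)])
    try:
        prior = em_unrestricted(
            Z,
            [model_i.unshrunk(), model_j.unshrunk()],
            _PAIR_CONFIGS,
            tol=tol,
            max_iter=max_iter,
        )
    except ValueError:
        warnings.warn("pairwise EM degenerate; falling back to independence")
        return (1.0 - model_i.pi0) * (1.0 - model_j.pi0)
    return float(prior.probs[3])


def study_correlation(a_i: float, a_j: float, a_ij: float) -> float:
    """Phi coefficient between two studies' non-null indicators.

    ``(a_ij - a_i a_j) / sqrt(a_i (1 - a_i) a_j (1 - a_j))`` clipped to
    [-1, 1]; returns 0 with a warning when a marginal is degenerate.
    """
    if not (0.0 < a_i < 1.0) or not (0.0 < a_j < 1.0):
        warnings.warn("degenerate marginal non-null probability; correlation set to 0")
        return 0.0
    r = (a_ij - a_i * a_j) / np.sqrt(a_i * (1.0 - a_i) * a_j * (1.0 - a_j))
    return float(np.clip(r, -1.0, 1.0))


def bootstrap_correlation(
    Z: StudyMatrix,
    i: int,
    j: int,
    models,
    B: int = 100,
    seed: int = 0,
    resampler=None,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> float:
    """Mean phi correlation of studies i, j over B bootstrap resamples.

    Each resample draws floor(n/2) genes with replacement (seeded from
    ``seed`` and the pair index); the joint prior is re-estimated on the
    resample while the marginals come from the per-study fitted models.
    ``resampler`` (a callable ``(rng, n) -> index array``) is a test hook.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(i), int(j)]))
    a_i = 1.0 - models[i].pi0
    a_j = 1.0 - models[j].pi0
    zi = Z.column(i)
    zj = Z.column(j)
    n = Z.n
    rs = []
    for _ in range(B):
        if resampler is None:
            idx = rng.integers(0, n, size=n // 2)
        else:
            idx = resampler(rng, n)
        a_ij = pairwise_joint_prior(
            zi[idx], zj[idx], models[i], models[j], tol=tol, max_iter=max_iter
        )
        rs.append(study_correlation(a_i, a_j, a_ij))
    return float(np.mean(rs))


def estimate_correlations(
    Z: StudyMatrix,
    models,
    B: int = 100,
    seed: int = 0,
    *,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> StudyCorrelation:
    """Bootstrap-mean phi correlations for every study pair."""
    m = Z.m
    a = np.array([1.0 - mod.pi0 for mod in models])
    r = np.eye(m)
    a_joint = np.diag(a).copy()
    for i in range(m):
        for j in range(i + 1, m):
            rij = bootstrap_correlation(
                Z, i, j, models, B=B, seed=seed, tol=tol, max_iter=max_iter
            )
            r[i, j] = r[j, i] = rij
            # back out the implied joint probability from the mean correlation
            a_joint[i, j] = a_joint[j, i] = a[i] * a[j] + rij * np.sqrt(
                a[i] * (1 - a[i]) * a[j] * (1 - a[j])
            )
    return StudyCorrelation(a, a_joint, r)


def cluster_studies(
    corr: StudyCorrelation,
    edge_threshold: float = 0.1,
    method: str = "infomap",
    seed: int = 0,
) -> ClusterPartition:
    """Partition studies by community detection on the thresholded graph.

    An unweighted edge joins studies with ``|r| >= edge_threshold``.
    ``method='infomap'`` runs seeded map-equation community detection;
    ``method='components'`` uses connected components.  Isolated studies
    become singleton clusters either way.
    """
    m = corr.r.shape[0]
    adj = (np.abs(corr.r) >= edge_threshold) & ~np.eye(m, dtype=bool)
    edges = [(i, j) for i in range(m) for j in range(i + 1, m) if adj[i, j]]

    if method == "components":
        labels = _component_labels(m, edges)
    elif method == "infomap":
        import random

        import igraph

        igraph.set_random_number_generator(random.Random(int(seed)))
        g = igraph.Graph(n=m, edges=edges)
        labels = np.asarray(g.community_infomap().membership)
    else:
        raise ValueError(f"unknown clustering method {method!r}")

    clusters = [
        sorted(np.flatnonzero(labels == lab).tolist()) for lab in np.unique(labels)
    ]
    clusters.sort(key=lambda c: (-len(c), c))
    return ClusterPartition(clusters, m)


def _component_labels(m: int, edges) -> np.ndarray:
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edges:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = [find(i) for i in range(m)]
    _, labels = np.unique(roots, return_inverse=True)
    return labels
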
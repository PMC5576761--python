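"""The full replicability pipeline: per-cluster EM, count-posterior merge,
and the three run modes (clustered, independence, single-cluster bound).

Per-cluster analyses produce, for every gene, the posterior distribution of
the number of non-null realizations inside the cluster.  Because clusters
are modelled as independent, the across-study count distribution is the
convolution of the per-cluster ones; fdr_k is the merged mass on counts
below k.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass

import numpy as np

from .clustering import ClusterPartition, cluster_studies, estimate_correlations
from .config_em import (
    ConfigurationPrior,
    all_configs,
    config_likelihoods,
    count_likelihood_table,
    em_restricted,
    em_unrestricted,
)
from .independent import FdrResult, count_posterior_independent
from .models import (
    Scale,
    StudyMatrix,
    estimate_power,
    fit_locfdr_style,
    fit_normix,
    pvals_to_zscores,
    shrink_f1,
)

__all__ = [
    "ClusterCountPosterior",
    "cluster_count_posteriors",
    "merge_count_tables",
    "merge_clusters",
    "fit_study_models",
    "screen",
]

log = logging.getLogger("screenrep")


@dataclass
class ClusterCountPosterior:
    """n x (|C|+1) table: entry [i, c] is P(gene i has c non-nulls in C)."""

    cluster: list
    table: np.ndarray
    is_bound: bool = False

    def __post_init__(self):
        self.cluster = [int(i) for i in self.cluster]
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape[1] != len(self.cluster) + 1:
            raise ValueError("table must have |C| + 1 count columns")
        if np.any(self.table < -1e-12):
            raise ValueError("count posteriors must be non-negative")


def cluster_count_posteriors(
    Z_C: StudyMatrix,
    models_C,
    n_H: int = 1024,
    *,
    prior: ConfigurationPrior | None = None,
    conservative: bool = False,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> ClusterCountPosterior:
    """Posterior distribution of the non-null count within one cluster.

    The configuration prior is fitted with the unrestricted EM when the
    full space fits in ``n_H`` configurations, otherwise with the
    restricted EM; prior fitting uses the unshrunk non-null densities (so
    the learned marginals agree with each study's pi0) while the per-gene
    posteriors apply the power-shrunk densities.  With a truncated prior
    the per-gene posterior is
    renormalized over the retained configurations (optimistic policy);
    ``conservative=True`` instead applies the epsilon correction count-wise
    so every entry upper-bounds the true count probability (rows then sum
    to >= 1 and merged fdr values are upper bounds).
    """
    c = Z_C.m
    if c < 1:
        raise ValueError("cluster must be non-empty")
    if prior is None:
        fit_models = [mod.unshrunk() for mod in models_C]
        if 2**c <= n_H:
            prior = em_unrestricted(
                Z_C, fit_models, all_configs(c), tol=tol, max_iter=max_iter
            )
        else:
            prior = em_restricted(Z_C, fit_models, n_H, tol=tol, max_iter=max_iter)

    L = config_likelihoods(Z_C, models_C, prior.configs)
    W = L * prior.probs
    weights = prior.weights
    eps = prior.exclusion_bound
    table = np.zeros((Z_C.n, c + 1))
    for cnt in range(c + 1):
        cols = weights == cnt
        if cols.any():
            table[:, cnt] = W[:, cols].sum(axis=1)
    denom = W.sum(axis=1)
    bad = denom <= 0.0
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} gene(s) have zero posterior mass on the retained "
            "configurations; assigning all mass to count 0"
        )
        denom = np.where(bad, 1.0, denom)
        table[bad] = 0.0
        table[bad, 0] = 1.0

    if conservative and eps > 0.0:
        # count-wise epsilon correction: numerator_c = sum_{|h|=c, retained}
        # L (pi - eps) + eps * (prior-free likelihood mass at count c)
        T = count_likelihood_table(Z_C, models_C)
        for cnt in range(c + 1):
            cols = weights == cnt
            retained = L[:, cols] @ (prior.probs[cols] - eps) if cols.any() else 0.0
            table[:, cnt] = np.maximum(retained, 0.0) + eps * T[:, cnt]
        table[bad] = 0.0
        table[bad, 0] = 1.0
        table = np.minimum(table / denom[:, None], 1.0)
        return ClusterCountPosterior(list(range(c)), table, is_bound=True)

    table = table / denom[:, None]
    return ClusterCountPosterior(list(range(c)), table, is_bound=False)


def merge_count_tables(tables) -> np.ndarray:
    """Convolve per-cluster count distributions along the count axis."""
    out = None
    for T in tables:
        T = np.asarray(T, dtype=float)
        if out is None:
            out = T
            continue
        n, a = out.shape
        b = T.shape[1]
        new = np.zeros((n, a + b - 1))
        for cb in range(b):  # direct polynomial product keeps exactness
            new[:, cb : cb + a] += out * T[:, cb : cb + 1]
        out = new
    return out


def merge_clusters(
    posteriors,
    k: int,
    gene_ids,
    threshold: float = 0.2,
) -> FdrResult:
    """fdr_k from independent per-cluster count posteriors.

    The merged count distribution is the convolution of the cluster tables;
    fdr_k is its mass on counts 0..k-1, capped at 1 (relevant when the
    cluster tables are conservative upper bounds).
    """
    total = sum(len(p.cluster) for p in posteriors)
    if not 1 <= k <= total + 1:
        raise ValueError(f"k must be in [1, {total + 1}]")
    merged = merge_count_tables([p.table for p in posteriors])
    fdr = np.minimum(merged[:, :k].sum(axis=1), 1.0)
    is_bound = any(p.is_bound for p in posteriors)
    return FdrResult(list(gene_ids), k, fdr, is_bound, threshold)


def fit_study_models(
    Z: StudyMatrix,
    estimator: str = "normix",
    null: str = "theoretical",
    *,
    power_shrinkage: bool = True,
):
    """Fit (and optionally power-shrink) a two-groups model per study.

    ``estimator='normix'`` fits the absolute-z half-normal mixture, with
    the null scale fixed at 1 for ``null='theoretical'``;
    ``estimator='locfdr_style'`` fits the signed-z empirical null chain.
    """
    models = []
    for j in range(Z.m):
        z = Z.column(j)
        if estimator == "normix":
            model = fit_normix(z, fix_null_scale=(null == "theoretical"))
        elif estimator == "locfdr_style":
            model = fit_locfdr_style(z)
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        if power_shrinkage:
            model = shrink_f1(model, estimate_power(model))
        models.append(model)
    return models


def _as_zscores(Z: StudyMatrix) -> StudyMatrix:
    return pvals_to_zscores(Z) if Z.scale is Scale.pvalue else Z


def screen(
    Z: StudyMatrix,
    ks,
    *,
    mode: str = "screen",
    models=None,
    estimator: str = "normix",
    null: str = "theoretical",
    power_shrinkage: bool = True,
    n_configs: int = 1024,
    edge_threshold: float = 0.1,
    bootstrap: int = 100,
    threshold: float = 0.2,
    seed: int = 0,
    cluster_method: str = "infomap",
    conservative: bool = False,
    partition: ClusterPartition | None = None,
):
    """Run the full replicability pipeline.

    Modes: ``screen`` (cluster studies, EM per cluster, merge by dynamic
    programming), ``screen-ind`` (exact fdr_k under independence), and
    ``repfdr-ub`` (all studies in one cluster; restricted EM and the
    epsilon upper bound).

    Returns ``(results, info)`` where ``results`` maps each requested k to
    an :class:`FdrResult` and ``info`` records fitted models, the study
    partition (if any), and stage timings.
    """
    if isinstance(ks, int):
        ks = [ks]
    ks = sorted(int(k) for k in ks)
    if any(k < 1 or k > Z.m + 1 for k in ks):
        raise ValueError(f"k values must be in [1, {Z.m + 1}]")

    info = {"timings": {}, "mode": mode}
    t0 = time.perf_counter()
    Zz = _as_zscores(Z)
    if models is None:
        models = fit_study_models(
            Zz, estimator=estimator, null=null, power_shrinkage=power_shrinkage
        )
    info["models"] = models
    info["timings"]["fit_models"] = time.perf_counter() - t0
    log.info("fitted %d study models in %.2fs", Zz.m, info["timings"]["fit_models"])

    results = {}
    if mode == "screen-ind":
        t0 = time.perf_counter()
        table = count_posterior_independent(Zz, models)
        for k in ks:
            fdr = np.clip(table[:, :k].sum(axis=1), 0.0, 1.0)
            results[k] = FdrResult(Zz.gene_ids, k, fdr, False, threshold)
        info["timings"]["fdr"] = time.perf_counter() - t0
    elif mode == "repfdr-ub":
        from .config_em import fdr_k_upper_bound_rows

        t0 = time.perf_counter()
        prior = em_restricted(Zz, [mod.unshrunk() for mod in models], n_configs)
        info["prior"] = prior
        info["timings"]["em"] = time.perf_counter() - t0
        t0 = time.perf_counter()
        for k in ks:
            fdr = fdr_k_upper_bound_rows(Zz, models, prior, k)
            results[k] = FdrResult(Zz.gene_ids, k, fdr, True, threshold)
        info["timings"]["fdr"] = time.perf_counter() - t0
    elif mode == "screen":
        if partition is None:
            t0 = time.perf_counter()
            corr = estimate_correlations(Zz, models, B=bootstrap, seed=seed)
            partition = cluster_studies(
                corr, edge_threshold, method=cluster_method, seed=seed
            )
            info["correlations"] = corr
            info["timings"]["clustering"] = time.perf_counter() - t0
            log.info(
                "clustered %d studies into %d clusters in %.2fs",
                Zz.m,
                partition.n_clusters,
                info["timings"]["clustering"],
            )
        info["partition"] = partition
        t0 = time.perf_counter()
        posteriors = []
        for members in partition.clusters:
            sub = Zz.subset_studies(members)
            sub_models = [models[j] for j in members]
            post = cluster_count_posteriors(
                sub, sub_models, n_H=n_configs, conservative=conservative
            )
            post.cluster = members
            posteriors.append(post)
        info["timings"]["cluster_em"] = time.perf_counter() - t0
        info["posteriors"] = posteriors
        t0 = time.perf_counter()
        for k in ks:
            results[k] = merge_clusters(posteriors, k, Zz.gene_ids, threshold)
        info["timings"]["merge"] = time.perf_counter() - t0
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return results, info
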
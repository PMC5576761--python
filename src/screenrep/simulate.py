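"""Synthetic multi-study p-value matrices with known ground truth.

Two generators are provided.  ``simulate_independent`` draws each study's
non-null genes independently and adds a fixed block of replicable genes.
``simulate_clustered`` induces dependence between studies by thresholding
a latent Gaussian matrix with a block-exchangeable correlation structure.
In both, null cells are Uniform(0,1) and non-null cells follow the 50/50
Beta(1,x)/Beta(x,1) mixture (low and high p-values respectively).

``true_fdr_clustered`` computes the generative-model posterior fdr_k for
the clustered scenario, usable as an oracle for the estimated values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import Scale, StudyMatrix

__all__ = [
    "SimulatedDataset",
    "sample_nonnull_p",
    "simulate_independent",
    "simulate_clustered",
    "true_fdr_clustered",
]


@dataclass
class SimulatedDataset:
    P: StudyMatrix
    H_true: np.ndarray  # n x m binary
    params: dict

    def __post_init__(self):
        self.H_true = np.asarray(self.H_true, dtype=np.int8)
        if self.H_true.shape != self.P.values.shape:
            raise ValueError("H_true shape must match the p-value matrix")

    def truth_counts(self) -> np.ndarray:
        return self.H_true.sum(axis=1)


def sample_nonnull_p(x: float, count: int, rng: np.random.Generator) -> np.ndarray:
    """Non-null p-values: 50/50 mixture of Beta(1, x) and Beta(x, 1)."""
    if x <= 1:
        raise ValueError("x must be > 1")
    low = rng.random(count) < 0.5
    out = np.empty(count)
    out[low] = rng.beta(1.0, x, size=int(low.sum()))
    out[~low] = rng.beta(x, 1.0, size=int((~low).sum()))
    return out


def _ids(n: int, m: int):
    return [f"g{i}" for i in range(n)], [f"s{j}" for j in range(m)]


def _fill_pvalues(H, x, rng, force_low=None):
    n, m = H.shape
    P = rng.random((n, m))
    nonnull = H.astype(bool)
    P[nonnull] = sample_nonnull_p(x, int(nonnull.sum()), rng)
    if force_low is not None:
        P[force_low] = rng.beta(1.0, x, size=int(force_low.sum()))
    return P


def simulate_independent(
    n: int = 5000,
    m: int = 20,
    per_study_nonnull: int = 300,
    replicable_genes: int = 50,
    extra_studies: int = 5,
    x: float = 100.0,
    seed: int = 0,
    extra_study_mode: str = "random",
) -> SimulatedDataset:
    """Independent-studies scenario.

    Each study gets ``per_study_nonnull`` random non-null genes (without
    replacement, independently across studies).  On top of that, a block of
    ``replicable_genes`` genes (indices 0..r-1) is forced non-null in
    ``extra_studies`` studies with low-tail Beta(1, x) p-values only.  With
    ``extra_study_mode='random'`` (default) the extra studies are drawn
    independently per gene, which leaves the study columns uncorrelated;
    ``'fixed'`` uses studies 0..e-1 for every replicable gene, which makes
    those studies genuinely correlated.
    """
    if extra_studies > m:
        raise ValueError("extra_studies cannot exceed m")
    rng = np.random.default_rng(seed)
    H = np.zeros((n, m), dtype=np.int8)
    for j in range(m):
        H[rng.choice(n, size=per_study_nonnull, replace=False), j] = 1
    force_low = np.zeros((n, m), dtype=bool)
    if extra_study_mode == "fixed":
        force_low[:replicable_genes, :extra_studies] = True
    elif extra_study_mode == "random":
        for i in range(replicable_genes):
            force_low[i, rng.choice(m, size=extra_studies, replace=False)] = True
    else:
        raise ValueError(f"unknown extra_study_mode {extra_study_mode!r}")
    H[force_low] = 1
    P = _fill_pvalues(H, x, rng, force_low)
    gene_ids, study_ids = _ids(n, m)
    return SimulatedDataset(
        StudyMatrix(P, gene_ids, study_ids, Scale.pvalue),
        H,
        {
            "scenario": "independent",
            "n": n,
            "m": m,
            "per_study_nonnull": per_study_nonnull,
            "replicable_genes": replicable_genes,
            "extra_studies": extra_studies,
            "extra_study_mode": extra_study_mode,
            "x": x,
            "seed": seed,
        },
    )


def simulate_clustered(
    n: int = 5000,
    M: int = 4,
    cluster_size: int = 10,
    r: float = 0.8,
    x: float = 100.0,
    quantile: float = 0.94,
    seed: int = 0,
) -> SimulatedDataset:
    """Dependent-studies scenario with M independent equicorrelated blocks.

    A latent n x (M * cluster_size) Gaussian matrix with within-block
    correlation ``r`` is thresholded at the standard-normal ``quantile`` to
    produce the truth matrix, so each study is non-null with probability
    ``1 - quantile`` (expected 300 non-nulls at the defaults).
    """
    if not 0.0 <= r < 1.0:
        raise ValueError("r must be in [0, 1)")
    rng = np.random.default_rng(seed)
    m = M * cluster_size
    tau = stats.norm.ppf(quantile)
    # A = sqrt(r) * block factor + sqrt(1 - r) * noise gives the
    # block-exchangeable correlation structure
    G = rng.standard_normal((n, M))
    E = rng.standard_normal((n, m))
    A = np.sqrt(r) * np.repeat(G, cluster_size, axis=1) + np.sqrt(1.0 - r) * E
    H = (A >= tau).astype(np.int8)
    P = _fill_pvalues(H, x, rng)
    gene_ids, study_ids = _ids(n, m)
    return SimulatedDataset(
        StudyMatrix(P, gene_ids, study_ids, Scale.pvalue),
        H,
        {
            "scenario": "clustered",
            "n": n,
            "M": M,
            "cluster_size": cluster_size,
            "r": r,
            "x": x,
            "quantile": quantile,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# generative-model oracle for the clustered scenario


def _exchangeable_config_prior(cluster_size: int, r: float, quantile: float, n_quad=96):
    """E[p(G)^c (1 - p(G))^(size-c)] for c = 0..size, by Gauss-Hermite.

    p(G) is the conditional non-null probability given the block factor G;
    the returned vector is the prior probability of any *single*
    configuration with c non-nulls (multiply by C(size, c) for the count
    prior).
    """
    tau = stats.norm.ppf(quantile)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    w = weights / np.sqrt(2.0 * np.pi)
    if r == 0.0:
        p = np.full(n_quad, stats.norm.sf(tau))
    else:
        p = stats.norm.sf((tau - np.sqrt(r) * nodes) / np.sqrt(1.0 - r))
    cs = np.arange(cluster_size + 1)
    vals = (p[None, :] ** cs[:, None]) * ((1.0 - p[None, :]) ** (cluster_size - cs)[:, None])
    return vals @ w


def _beta_mixture_pdf(p: np.ndarray, x: float) -> np.ndarray:
    return 0.5 * stats.beta.pdf(p, 1.0, x) + 0.5 * stats.beta.pdf(p, x, 1.0)


def true_fdr_clustered(dataset: SimulatedDataset, k: int) -> np.ndarray:
    """Exact generative posterior fdr_k for a clustered-scenario dataset.

    Uses the known block-exchangeable configuration prior and the known
    null (uniform) and non-null (Beta mixture) p-value densities; per-block
    count posteriors are combined across the independent blocks by
    convolution.
    """
    params = dataset.params
    if params.get("scenario") != "clustered":
        raise ValueError("oracle applies to clustered-scenario datasets only")
    M, size = params["M"], params["cluster_size"]
    r, x, quantile = params["r"], params["x"], params["quantile"]
    cfg_prior = _exchangeable_config_prior(size, r, quantile)

    P = dataset.P.values
    n = P.shape[0]
    tables = []
    for b in range(M):
        block = P[:, b * size : (b + 1) * size]
        f1 = _beta_mixture_pdf(block, x)
        # count-indexed DP over the block with f0 = 1 (uniform null)
        T = np.zeros((n, size + 1))
        T[:, 0] = 1.0
        for j in range(size):
            new = T.copy()
            new[:, 1:] += f1[:, j : j + 1] * T[:, :-1]
            T = new
        post = T * cfg_prior[None, :]
        tables.append(post / post.sum(axis=1, keepdims=True))

    merged = tables[0]
    for T in tables[1:]:
        n_, a = merged.shape
        b_ = T.shape[1]
        new = np.zeros((n_, a + b_ - 1))
        for cb in range(b_):
            new[:, cb : cb + a] += merged * T[:, cb : cb + 1]
        merged = new
    return np.clip(merged[:, :k].sum(axis=1), 0.0, 1.0)
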
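"""EM estimation of the prior over binary study-configurations.

``em_unrestricted`` fits a categorical prior over an arbitrary support of
configurations by plain EM (the E-step computes per-gene posteriors over
the support; the M-step averages them).  ``em_restricted`` grows the
support one study at a time, keeping only the highest-probability
configurations, and tracks the retained prior mass (xi) and a bound on any
excluded configuration's probability (epsilon).  These feed the provable
fdr_k upper bound implemented in :func:`fdr_k_upper_bound`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .independent import _count_table
from .models import StudyMatrix, TwoGroupsModel

__all__ = [
    "ConfigurationPrior",
    "config_likelihoods",
    "em_unrestricted",
    "em_restricted",
    "count_likelihood_table",
    "likelihood_sum_below_k",
    "fdr_k_upper_bound",
]

_LOG_TINY = math.log(1e-300)


@dataclass
class ConfigurationPrior:
    """A prior over a retained set of binary configurations.

    ``retained_mass`` (xi) is the total prior probability of the retained
    configurations; ``exclusion_bound`` (epsilon) bounds the prior of any
    configuration that was dropped along the way.  For an untruncated fit
    xi = 1 and epsilon = 0.
    """

    configs: np.ndarray  # (n_cfg, l) 0/1
    probs: np.ndarray
    retained_mass: float = 1.0
    exclusion_bound: float = 0.0
    capacity: int | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.configs = np.asarray(self.configs, dtype=np.int8)
        if self.configs.ndim != 2:
            raise ValueError("configs must be a 2-d binary array")
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.configs.shape[0],):
            raise ValueError("probs length must match number of configs")
        if self.probs.sum() > 1.0 + 1e-9:
            raise ValueError("probabilities sum to more than 1")
        if self.capacity is not None and self.configs.shape[0] > self.capacity:
            raise ValueError("more configurations than capacity")

    @property
    def n_studies(self) -> int:
        return self.configs.shape[1]

    @property
    def weights(self) -> np.ndarray:
        return self.configs.sum(axis=1)


def _values(Z) -> np.ndarray:
    return Z.values if isinstance(Z, StudyMatrix) else np.asarray(Z, dtype=float)


def _log_density_pair(Z, models):
    V = _values(Z)
    n, m = V.shape
    if len(models) != m:
        raise ValueError("need one model per study")
    LF0 = np.empty((n, m))
    LF1 = np.empty((n, m))
    for j, model in enumerate(models):
        LF0[:, j] = np.log(np.maximum(model.f0(V[:, j]), 1e-300))
        LF1[:, j] = np.log(np.maximum(model.f1(V[:, j]), 1e-300))
    return LF0, LF1


def config_likelihoods(Z, models, configs) -> np.ndarray:
    """n x n_cfg matrix of P(Z row | configuration)."""
    configs = np.asarray(configs, dtype=float)
    LF0, LF1 = _log_density_pair(Z, models)
    logL = LF0 @ (1.0 - configs.T) + LF1 @ configs.T
    return np.exp(np.maximum(logL, _LOG_TINY))


def all_configs(m: int) -> np.ndarray:
    """All 2^m binary configurations of length m, in lexicographic order."""
    if m == 0:
        return np.zeros((1, 0), dtype=np.int8)
    grid = np.indices((2,) * m).reshape(m, -1).T
    return np.ascontiguousarray(grid, dtype=np.int8)


def em_unrestricted(
    Z,
    models,
    configs=None,
    *,
    init=None,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> ConfigurationPrior:
    """EM over an explicit configuration support.

    Starts from the uniform distribution over the support (or ``init``);
    the observed-data log-likelihood is non-decreasing across iterations
    and iteration stops when its change drops below ``tol``.  Genes whose
    likelihood is zero under every supported configuration are dropped with
    a warning.
    """
    V = _values(Z)
    if configs is None:
        configs = all_configs(V.shape[1])
    configs = np.asarray(configs, dtype=np.int8)
    n_cfg = configs.shape[0]
    if n_cfg == 0:
        raise ValueError("support must be non-empty")

    L = config_likelihoods(V, models, configs)
    ok = L.sum(axis=1) > 0.0
    if not ok.all():
        warnings.warn(
            f"dropping {int((~ok).sum())} gene(s) with zero likelihood under "
            "every supported configuration"
        )
        L = L[ok]
    if L.shape[0] == 0:
        raise ValueError("no gene has positive likelihood on the support")

    if init is None:
        pi = np.full(n_cfg, 1.0 / n_cfg)
    else:
        pi = np.asarray(init, dtype=float)
        if pi.shape != (n_cfg,) or pi.sum() <= 0.0:
            raise ValueError("invalid EM initialization")
        pi = pi / pi.sum()

    trace = []
    converged = False
    for _ in range(max_iter):
        s = L @ pi  # per-gene mixture likelihood
        good = s > 0.0
        if not good.all():  # can happen after a prior component hits zero
            L = L[good]
            s = s[good]
        trace.append(float(np.log(s).sum()))
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        # M-step: pi_j <- pi_j * mean_i L_ij / s_i  (two BLAS products,
        # no n x n_cfg temporaries)
        pi = pi * (L.T @ (1.0 / s)) / L.shape[0]
    if not converged and max_iter > 1:
        warnings.warn("configuration EM did not converge; returning best iterate")

    return ConfigurationPrior(
        configs,
        pi,
        retained_mass=1.0,
        exclusion_bound=0.0,
        info={"loglik_trace": trace, "converged": converged},
    )


def _retain_top(configs, probs, keep: int):
    """Indices of the top-``keep`` probabilities; ties keep the
    lexicographically smallest bit-vectors so exactly ``keep`` survive."""
    order = sorted(
        range(len(probs)), key=lambda c: (-probs[c], tuple(configs[c].tolist()))
    )
    kept = sorted(order[:keep])
    dropped = sorted(order[keep:])
    return kept, dropped


def em_restricted(
    Z,
    models,
    n_H: int = 1024,
    *,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> ConfigurationPrior:
    """Capacity-limited EM over study configurations.

    Studies are introduced one at a time.  Each round extends every
    retained configuration by 0 and 1, refits the prior by EM (warm-started
    by splitting each parent's probability equally between its two
    children), rescales by the retained mass, and truncates back to the top
    ``n_H / 2`` configurations.  No truncation is applied when the support
    still fits (in particular on the final round), so ``n_H >= 2^m``
    reproduces the unrestricted EM with xi = 1 and epsilon = 0.
    """
    V = _values(Z)
    m = V.shape[1]
    if n_H < 4:
        raise ValueError("n_H must be at least 4")
    if n_H & (n_H - 1) != 0:
        n_H = 2 ** int(math.floor(math.log2(n_H)))
        warnings.warn(f"n_H is not a power of two; rounding down to {n_H}")

    if 2**m <= n_H:
        prior = em_unrestricted(V, models, all_configs(m), tol=tol, max_iter=max_iter)
        prior.capacity = n_H
        return prior

    l0 = int(math.log2(n_H)) - 1
    configs = all_configs(l0)
    fit = em_unrestricted(V[:, :l0], models[:l0], configs, tol=tol, max_iter=max_iter)
    probs = fit.probs  # absolute scale; sums to xi
    xi = 1.0
    eps = 0.0
    trace = list(fit.info["loglik_trace"])

    for l in range(l0, m):
        ext = np.repeat(configs, 2, axis=0)
        ext = np.hstack([ext, np.tile([[0], [1]], (configs.shape[0], 1))]).astype(
            np.int8
        )
        init = np.repeat(probs / probs.sum(), 2) / 2.0
        fit = em_unrestricted(
            V[:, : l + 1], models[: l + 1], ext, init=init, tol=tol, max_iter=max_iter
        )
        trace.extend(fit.info["loglik_trace"])
        pihat = xi * fit.probs  # update (1): rescale to absolute prior mass
        if l + 1 < m and ext.shape[0] > n_H // 2:
            kept, dropped = _retain_top(ext, pihat, n_H // 2)  # update (2)
            if dropped:
                eps = max(eps, float(pihat[dropped].max()))  # update (4)
            configs = ext[kept]
            probs = pihat[kept]
        else:
            configs = ext
            probs = pihat
        xi = float(probs.sum())  # update (3)

    return ConfigurationPrior(
        configs,
        probs,
        retained_mass=xi,
        exclusion_bound=eps,
        capacity=n_H,
        info={"loglik_trace": trace},
    )


def count_likelihood_table(Z, models) -> np.ndarray:
    """n x (m+1) table of prior-free likelihood sums by non-null count.

    Column c holds sum over all configurations with exactly c non-nulls of
    the product of per-study densities (f0 or f1).
    """
    V = _values(Z)
    n, m = V.shape
    F0 = np.empty((n, m))
    F1 = np.empty((n, m))
    for j, model in enumerate(models):
        F0[:, j] = model.f0(V[:, j])
        F1[:, j] = model.f1(V[:, j])
    return _count_table(F0, F1)


def likelihood_sum_below_k(z_row, models, k: int) -> float:
    """Sum over all configurations with fewer than k non-nulls of P(z | h)."""
    z_row = np.atleast_2d(np.asarray(z_row, dtype=float))
    m = z_row.shape[1]
    if not 1 <= k <= m + 1:
        raise ValueError(f"k must be in [1, {m + 1}]")
    T = count_likelihood_table(z_row, models)
    return float(T[0, :k].sum())


def fdr_k_upper_bound_rows(Z, models, prior: ConfigurationPrior, k: int) -> np.ndarray:
    """Vectorized fdr_k upper bound for every row of Z (see
    :func:`fdr_k_upper_bound`)."""
    V = np.atleast_2d(_values(Z))
    m = V.shape[1]
    if prior.n_studies != m:
        raise ValueError("prior configuration length must equal number of studies")
    if not 1 <= k <= m + 1:
        raise ValueError(f"k must be in [1, {m + 1}]")
    eps = prior.exclusion_bound

    L = config_likelihoods(V, models, prior.configs)  # n x n_cfg
    below = prior.weights < k
    term1 = L[:, below] @ (prior.probs[below] - eps)
    denom = L @ prior.probs
    if eps > 0.0:
        T = count_likelihood_table(V, models)
        term2 = eps * T[:, :k].sum(axis=1)
    else:
        term2 = 0.0
    out = np.ones(V.shape[0])
    good = denom > 0.0
    if not good.all():
        warnings.warn("zero posterior denominator for some gene(s); bound set to 1")
    np.divide(term1 + term2, denom, out=out, where=good)
    return np.clip(out, 0.0, 1.0)


def fdr_k_upper_bound(z_row, models, prior: ConfigurationPrior, k: int) -> float:
    """Provable upper bound on fdr_k from a truncated configuration prior.

    With the full support and epsilon = 0 this equals the exact fdr_k; in
    general the excluded configurations are accounted for by the epsilon
    term, computed with the prior-free count dynamic program.  The raw
    bound can exceed 1 and is capped.
    """
    return float(fdr_k_upper_bound_rows(np.atleast_2d(z_row), models, prior, k)[0])
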
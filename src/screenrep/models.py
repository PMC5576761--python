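"""Single-study two-groups models.

Each study's statistics are modelled as a mixture of a null density ``f0``
(prior ``pi0``) and a non-null density ``f1``.  The local false discovery
rate of an observation ``z`` is ``pi0 * f0(z) / f(z)`` where
``f = pi0 * f0 + (1 - pi0) * f1``.

Two estimators are provided:

* :func:`fit_normix` -- EM fit on absolute z-scores of a half-normal null
  (scale >= 1) plus a normal non-null component (location > 0).
* :func:`fit_locfdr_style` -- empirical-null fit of signed z-scores: normal
  null estimated on the central region by maximum likelihood, falling back
  to central matching and then to the theoretical N(0,1) null.

A study's estimated power (expected tdr under ``f1``) can be used to shrink
``f1`` pointwise; the shrunken ``f1`` is deliberately *not* renormalized.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

__all__ = [
    "Scale",
    "StudyMatrix",
    "Density",
    "TwoGroupsModel",
    "pvals_to_zscores",
    "fit_normix",
    "fit_locfdr_style",
    "estimate_power",
    "shrink_f1",
    "local_fdr",
]

#: p-values are clipped into [P_CLIP, 1 - P_CLIP] before the z transform so
#: that the resulting z-scores stay finite in double precision.
P_CLIP = 1e-15

_TINY = 1e-300


class Scale(str, enum.Enum):
    """Scale of the cells of a :class:`StudyMatrix`."""

    pvalue = "pvalue"
    zscore = "zscore"


class MatrixError(ValueError):
    """Raised for malformed study matrices."""


@dataclass
class StudyMatrix:
    """An n-genes x m-studies matrix of p-values or z-scores."""

    values: np.ndarray
    gene_ids: list
    study_ids: list
    scale: Scale = Scale.zscore

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.study_ids = list(self.study_ids)
        self.scale = Scale(self.scale)
        if self.values.ndim != 2:
            raise MatrixError("matrix must be two-dimensional")
        n, m = self.values.shape
        if n != len(self.gene_ids) or m != len(self.study_ids):
            raise MatrixError("label lengths do not match matrix shape")
        if n < 2:
            raise MatrixError("need at least 2 genes")
        if m < 1:
            raise MatrixError("need at least 1 study")
        if len(set(self.gene_ids)) != n:
            dupes = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise MatrixError(f"duplicate gene id(s): {dupes[:5]}")
        bad = ~np.isfinite(self.values)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise MatrixError(
                f"non-finite cell for gene {self.gene_ids[i]!r} in study "
                f"{self.study_ids[j]!r}"
            )
        if self.scale is Scale.pvalue:
            out = (self.values < 0.0) | (self.values > 1.0)
            if out.any():
                i, j = map(int, np.argwhere(out)[0])
                raise MatrixError(
                    f"p-value out of (0,1) for gene {self.gene_ids[i]!r} in "
                    f"study {self.study_ids[j]!r}"
                )
            self.values = np.clip(self.values, P_CLIP, 1.0 - P_CLIP)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.values[:, j]

    def subset_studies(self, idx) -> "StudyMatrix":
        idx = list(idx)
        return StudyMatrix(
            self.values[:, idx],
            self.gene_ids,
            [self.study_ids[j] for j in idx],
            self.scale,
        )


def pvals_to_zscores(P: StudyMatrix) -> StudyMatrix:
    """One-tailed p-to-z transform, ``z = Phi^{-1}(1 - p)`` cellwise.

    P-values are clipped into ``[1e-15, 1 - 1e-15]`` first, so the result is
    always finite.  The mapping is monotone decreasing in p; one-tailed
    p-values near 1 map to large negative z.
    """
    if P.scale is not Scale.pvalue:
        raise MatrixError("input matrix is not on the p-value scale")
    p = np.clip(P.values, P_CLIP, 1.0 - P_CLIP)
    z = stats.norm.isf(p)
    return StudyMatrix(z, P.gene_ids, P.study_ids, Scale.zscore)


# ---------------------------------------------------------------------------
# densities


@dataclass
class Density:
    """A small serializable density spec.

    kinds:
      ``normal``      params (loc, scale), support R
      ``halfnormal``  params (scale,), support [0, inf)
      ``grid``        params (xs, ys): linear interpolation, 0 outside
      ``zero``        the all-zero "density" (used for power-0 shrinkage)
    """

    kind: str
    params: tuple = ()

    def pdf(self, z):
        z = np.asarray(z, dtype=float)
        if self.kind == "normal":
            loc, scale = self.params
            return stats.norm.pdf(z, loc, scale)
        if self.kind == "halfnormal":
            (scale,) = self.params
            return stats.halfnorm.pdf(z, scale=scale)
        if self.kind == "grid":
            xs, ys = self.params
            return np.interp(z, xs, ys, left=0.0, right=0.0)
        if self.kind == "zero":
            return np.zeros_like(z)
        raise ValueError(f"unknown density kind {self.kind!r}")


class Domain(str, enum.Enum):
    signed_z = "signed_z"
    absolute_z = "absolute_z"


@dataclass
class TwoGroupsModel:
    """Fitted two-groups model for one study.

    ``domain`` records whether the densities live on signed z-scores or on
    absolute z-scores; in the latter case all evaluation methods take the
    absolute value of their argument first, so callers may always pass the
    signed scores.  ``shrink`` is the pointwise multiplier applied to the
    non-null density (power shrinkage); it is intentionally not a density
    renormalization.
    """

    pi0: float
    null: Density
    nonnull: Density
    domain: Domain = Domain.absolute_z
    power: float | None = None
    shrink: float = 1.0
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.domain = Domain(self.domain)
        if not 0.0 <= self.pi0 <= 1.0:
            raise ValueError("pi0 must be in [0, 1]")

    def _x(self, z):
        z = np.asarray(z, dtype=float)
        return np.abs(z) if self.domain is Domain.absolute_z else z

    def f0(self, z):
        return self.null.pdf(self._x(z))

    def f1(self, z):
        return self.shrink * self.nonnull.pdf(self._x(z))

    def f(self, z):
        return self.pi0 * self.f0(z) + (1.0 - self.pi0) * self.f1(z)

    def local_fdr(self, z):
        return local_fdr(self, z)

    def tdr(self, z):
        return 1.0 - local_fdr(self, z)

    def unshrunk(self) -> "TwoGroupsModel":
        """Copy of the model with the f1 shrinkage multiplier reset to 1."""
        return replace(self, shrink=1.0)

    # -- plain-text serialization ------------------------------------------
    def to_text(self) -> str:
        lines = [
            f"pi0\t{self.pi0!r}",
            f"domain\t{self.domain.value}",
            f"power\t{'' if self.power is None else repr(self.power)}",
            f"shrink\t{self.shrink!r}",
        ]
        for name, dens in (("null", self.null), ("nonnull", self.nonnull)):
            lines.append(f"{name}.kind\t{dens.kind}")
            if dens.kind == "grid":
                xs, ys = dens.params
                lines.append(f"{name}.xs\t" + ",".join(repr(float(v)) for v in xs))
                lines.append(f"{name}.ys\t" + ",".join(repr(float(v)) for v in ys))
            else:
                lines.append(
                    f"{name}.params\t" + ",".join(repr(float(v)) for v in dens.params)
                )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "TwoGroupsModel":
        kv = {}
        for line in text.splitlines():
            if line.strip():
                key, _, val = line.partition("\t")
                kv[key] = val
        densities = {}
        for name in ("null", "nonnull"):
            kind = kv[f"{name}.kind"]
            if kind == "grid":
                xs = np.array([float(v) for v in kv[f"{name}.xs"].split(",")])
                ys = np.array([float(v) for v in kv[f"{name}.ys"].split(",")])
                densities[name] = Density("grid", (xs, ys))
            else:
                params = tuple(
                    float(v) for v in kv[f"{name}.params"].split(",") if v != ""
                )
                densities[name] = Density(kind, params)
        return cls(
            pi0=float(kv["pi0"]),
            null=densities["null"],
            nonnull=densities["nonnull"],
            domain=Domain(kv["domain"]),
            power=None if kv.get("power", "") == "" else float(kv["power"]),
            shrink=float(kv.get("shrink", "1.0")),
        )


def local_fdr(model: TwoGroupsModel, z):
    """Posterior null probability ``pi0 f0(z) / f(z)``; 1 where ``f(z) = 0``."""
    num = model.pi0 * model.f0(z)
    den = model.f(z)
    num, den = np.broadcast_arrays(np.asarray(num, float), np.asarray(den, float))
    out = np.ones_like(den)
    ok = den > 0.0
    if not ok.all():
        warnings.warn("f(z) = 0 at some points; local fdr set to 1 there")
    np.divide(num, den, out=out, where=ok)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# normix: half-normal null + normal non-null EM on |z|


def fit_normix(
    z,
    *,
    fix_null_scale: bool = False,
    min_len: int = 100,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> TwoGroupsModel:
    """EM fit of ``pi0 * HalfNormal(s) + (1 - pi0) * Normal(mu, sigma1)`` to |z|.

    The null scale is constrained to ``s >= 1`` (projection at each M-step)
    and the non-null location to ``mu > 0``.  With ``fix_null_scale=True``
    the null is pinned at the theoretical half-normal (``s = 1``).

    Raises on fewer than ``min_len`` observations or degenerate (constant)
    input; warns when EM does not converge within ``max_iter``.
    """
    x = np.abs(np.asarray(z, dtype=float).ravel())
    if x.size < min_len:
        raise ValueError(f"need at least {min_len} observations, got {x.size}")
    if np.ptp(x) == 0.0:
        raise ValueError("degenerate input: all values identical")

    pi0 = 0.9
    s = 1.0
    mu = max(float(np.percentile(x, 75)), 1e-3)
    sig1 = 1.0

    trace = []
    converged = False
    for _ in range(max_iter):
        g0 = pi0 * stats.halfnorm.pdf(x, scale=s)
        g1 = (1.0 - pi0) * stats.norm.pdf(x, mu, sig1)
        tot = g0 + g1
        tot = np.where(tot > 0.0, tot, _TINY)
        ll = float(np.log(tot).sum())
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        r0 = g0 / tot
        r1 = 1.0 - r0
        w0 = r0.sum()
        w1 = r1.sum()
        pi0 = w0 / x.size
        if not fix_null_scale and w0 > 0.0:
            s = max(1.0, math.sqrt(float((r0 * x**2).sum() / w0)))
        if w1 > 0.0:
            mu = max(float((r1 * x).sum() / w1), 1e-3)
            sig1 = max(math.sqrt(float((r1 * (x - mu) ** 2).sum() / w1)), 0.05)
    if not converged:
        warnings.warn("normix EM did not converge; returning best iterate")

    model = TwoGroupsModel(
        pi0=float(np.clip(pi0, 0.0, 1.0)),
        null=Density("halfnormal", (s,)),
        nonnull=Density("normal", (mu, sig1)),
        domain=Domain.absolute_z,
        fit_info={
            "method": "normix",
            "loglik_trace": trace,
            "iterations": len(trace),
            "converged": converged,
            "data_absmax": float(x.max()),
        },
    )
    return model


# ---------------------------------------------------------------------------
# locfdr-style empirical null on signed z


_CENTRAL = 2.0


def _mle_empirical_null(z: np.ndarray):
    """Efron-style MLE of a normal null from the central region |z| <= 2."""
    zc = z[np.abs(z) <= _CENTRAL]
    if zc.size < 10:
        raise RuntimeError("too few central observations")
    n0 = zc.size

    def nll(theta):
        delta, log_sigma = theta
        sigma = math.exp(log_sigma)
        pa = stats.norm.cdf((_CENTRAL - delta) / sigma) - stats.norm.cdf(
            (-_CENTRAL - delta) / sigma
        )
        if pa <= 0.0:
            return np.inf
        return -(
            stats.norm.logpdf(zc, delta, sigma).sum() - n0 * math.log(pa)
        )

    res = optimize.minimize(
        nll, x0=np.array([float(np.median(zc)), 0.0]), method="Nelder-Mead"
    )
    delta, sigma = float(res.x[0]), float(math.exp(res.x[1]))
    pa = stats.norm.cdf((_CENTRAL - delta) / sigma) - stats.norm.cdf(
        (-_CENTRAL - delta) / sigma
    )
    pi0 = (n0 / z.size) / pa
    return delta, sigma, pi0


def _central_matching(z: np.ndarray):
    """Quadratic fit to log bin counts of the central region."""
    counts, edges = np.histogram(z[np.abs(z) <= _CENTRAL], bins=20)
    mids = 0.5 * (edges[:-1] + edges[1:])
    keep = counts > 0
    if keep.sum() < 5:
        raise RuntimeError("too few occupied bins for central matching")
    coef = np.polyfit(mids[keep], np.log(counts[keep]), 2)
    c, b, a = coef[0], coef[1], coef[2]
    if c >= 0.0:
        raise RuntimeError("central log-density not concave")
    sigma = math.sqrt(-1.0 / (2.0 * c))
    delta = -b / (2.0 * c)
    bw = edges[1] - edges[0]
    # peak of fitted quadratic = log(n * bw * pi0 / (sqrt(2 pi) sigma))
    peak = a - b**2 / (4.0 * c)
    pi0 = math.exp(peak) * math.sqrt(2.0 * math.pi) * sigma / (z.size * bw)
    return delta, sigma, pi0


def _theoretical_pi0(z: np.ndarray) -> float:
    """Fraction-near-zero plug-in for pi0 under a theoretical N(0,1) null."""
    frac = float(np.mean(np.abs(z) <= 1.0))
    p_central = stats.norm.cdf(1.0) - stats.norm.cdf(-1.0)
    return min(1.0, frac / p_central)


def fit_locfdr_style(z, *, min_len_empirical: int = 200) -> TwoGroupsModel:
    """Empirical-null two-groups fit of signed z-scores.

    Tries a central-region MLE normal null first; if the implied pi0 exceeds
    1 it retries central matching; if that also fails it falls back to the
    theoretical N(0,1) null with a fraction-near-zero pi0 plug-in.  The
    branch actually taken is recorded in ``fit_info['branch']``.

    Fewer than ``min_len_empirical`` points skips the empirical-null fits.
    """
    z = np.asarray(z, dtype=float).ravel()
    if np.ptp(z) == 0.0:
        raise ValueError("degenerate input: all values identical")

    branch = None
    delta = 0.0
    sigma = 1.0
    pi0 = None
    if z.size >= min_len_empirical:
        try:
            delta, sigma, pi0 = _mle_empirical_null(z)
            branch = "mle"
        except RuntimeError:
            pi0 = None
        if pi0 is None or pi0 > 1.0:
            try:
                delta, sigma, pi0 = _central_matching(z)
                branch = "central_matching"
            except RuntimeError:
                pi0 = None
    if pi0 is None or pi0 > 1.0:
        delta, sigma = 0.0, 1.0
        pi0 = _theoretical_pi0(z)
        branch = "theoretical"
    pi0 = float(np.clip(pi0, 0.0, 1.0))

    # empirical f1 on a grid: (fhat - pi0 f0)+ / (1 - pi0)
    lo, hi = float(z.min()) - 1.0, float(z.max()) + 1.0
    xs = np.linspace(lo, hi, 1001)
    kde = stats.gaussian_kde(z)
    fhat = kde(xs)
    f0v = stats.norm.pdf(xs, delta, sigma)
    if pi0 < 1.0:
        ys = np.clip((fhat - pi0 * f0v) / (1.0 - pi0), 0.0, None)
        area = float(np.trapezoid(ys, xs))
        if area > 0.0:
            ys = ys / area
        nonnull = Density("grid", (xs, ys))
    else:
        nonnull = Density("zero")

    return TwoGroupsModel(
        pi0=pi0,
        null=Density("normal", (delta, sigma)),
        nonnull=nonnull,
        domain=Domain.signed_z,
        fit_info={
            "method": "locfdr_style",
            "branch": branch,
            "data_absmax": float(np.abs(z).max()),
        },
    )


# ---------------------------------------------------------------------------
# power and shrinkage


def _power_grid(model: TwoGroupsModel, n_grid: int = 2001) -> np.ndarray:
    hi = float(model.fit_info.get("data_absmax", 0.0))
    if model.nonnull.kind == "normal":
        loc, scale = model.nonnull.params
        hi = max(hi, abs(loc) + 8.0 * scale)
    elif model.nonnull.kind == "grid":
        hi = max(hi, float(np.abs(model.nonnull.params[0]).max()))
    hi = max(hi, 10.0) + 5.0
    if model.domain is Domain.absolute_z:
        return np.linspace(0.0, hi, n_grid)
    return np.linspace(-hi, hi, n_grid)


def estimate_power(model: TwoGroupsModel, n_grid: int = 2001) -> float:
    """Estimated power: expected tdr under the (unshrunk) non-null density.

    Computed by trapezoidal integration of ``f1(z) * tdr(z)`` on a fixed
    grid, normalized by the grid mass of ``f1``.  Defined as 0 when
    ``pi0 = 1`` or ``f1`` carries no mass on the grid.
    """
    if model.pi0 >= 1.0:
        return 0.0
    xs = _power_grid(model, n_grid)
    f1 = model.nonnull.pdf(xs)  # unshrunk
    mass = float(np.trapezoid(f1, xs))
    if mass <= 0.0:
        return 0.0
    tdr = 1.0 - local_fdr(model, xs)
    power = float(np.trapezoid(f1 * tdr, xs)) / mass
    return float(np.clip(power, 0.0, 1.0))


def shrink_f1(model: TwoGroupsModel, power: float | None = None) -> TwoGroupsModel:
    """Multiply the non-null density by the study's estimated power.

    The result is used unrenormalized downstream, so shrinkage inflates
    local fdr values of weak studies.
    """
    if power is None:
        power = model.power if model.power is not None else estimate_power(model)
    if not 0.0 <= power <= 1.0:
        raise ValueError("power must be in [0, 1]")
    return replace(model, power=power, shrink=model.shrink * power)
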
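"""Comparison methods: Fisher meta-analysis, per-study BH counting, and the
expected-non-null-count (tdr sum) statistic."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import P_CLIP, Scale, StudyMatrix

__all__ = ["BaselineResult", "fisher_meta", "bh_count", "exp_count"]


@dataclass
class BaselineResult:
    """Per-gene statistic plus a selection call."""

    gene_ids: list
    statistic: np.ndarray
    selected: np.ndarray
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        self.statistic = np.asarray(self.statistic)
        self.selected = np.asarray(self.selected, dtype=bool)


def fisher_meta(P: StudyMatrix, q_threshold: float = 0.1) -> BaselineResult:
    """Fisher's combined chi-square test per gene, BH-corrected over genes.

    The statistic is the combined p-value from chi2(2m); selection is at
    BH q <= ``q_threshold``.  Combined p-values and q-values are stored in
    ``extra``.
    """
    if P.scale is not Scale.pvalue:
        raise ValueError("Fisher meta-analysis needs p-values")
    p = np.clip(P.values, P_CLIP, 1.0)
    X = -2.0 * np.log(p).sum(axis=1)
    combined = stats.chi2.sf(X, 2 * P.m)
    _, qvals, _, _ = multipletests(combined, method="fdr_bh")
    return BaselineResult(
        P.gene_ids,
        combined,
        qvals <= q_threshold,
        extra={"chi2": X, "qvalues": qvals},
    )


def bh_count(
    P: StudyMatrix, q_threshold: float = 0.1, k: int | None = None
) -> BaselineResult:
    """Number of studies in which a gene passes BH at ``q_threshold``.

    BH is applied over genes within each study separately.  When ``k`` is
    given, genes with count >= k are selected.
    """
    if P.scale is not Scale.pvalue:
        raise ValueError("BH counting needs p-values")
    q = np.empty_like(P.values)
    for j in range(P.m):
        _, q[:, j], _, _ = multipletests(P.values[:, j], method="fdr_bh")
    counts = (q <= q_threshold).sum(axis=1)
    selected = counts >= k if k is not None else np.zeros(P.n, dtype=bool)
    return BaselineResult(P.gene_ids, counts, selected, extra={"qvalues": q})


def exp_count(Z: StudyMatrix, models, k: float | None = None) -> BaselineResult:
    """Sum of marginal tdr values per gene.

    A (biased) estimator of the expected number of non-null realizations;
    equals the posterior-expected non-null count under the independence
    product prior.  When ``k`` is given, genes with statistic >= k are
    selected.
    """
    if len(models) != Z.m:
        raise ValueError("need one fitted model per study")
    tdr = np.column_stack(
        [1.0 - models[j].local_fdr(Z.column(j)) for j in range(Z.m)]
    )
    total = tdr.sum(axis=1)
    selected = total >= k if k is not None else np.zeros(Z.n, dtype=bool)
    return BaselineResult(Z.gene_ids, total, selected)
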
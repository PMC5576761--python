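"""Scoring of method outputs against a known truth matrix, plus the
up/down/mixed direction calls used for signed test statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .models import StudyMatrix

__all__ = ["EvaluationRow", "fdp_jaccard", "direction_calls", "rank_vs_fisher"]


@dataclass
class EvaluationRow:
    method: str
    k: int
    fdp: float
    jaccard: float
    n_selected: int


def fdp_jaccard(selected, H_true, k: int):
    """Empirical FDP and Jaccard of a selection against the truth matrix.

    The truth set is the genes with at least k non-null entries in
    ``H_true``.  ``selected`` is a boolean vector or an index/set of gene
    positions.  The FDP of an empty selection is 0 by convention.
    """
    H_true = np.asarray(H_true)
    n = H_true.shape[0]
    truth = set(np.flatnonzero(H_true.sum(axis=1) >= k).tolist())
    sel = np.asarray(selected)
    if sel.dtype == bool:
        if sel.shape != (n,):
            raise ValueError("boolean selection must have one entry per gene")
        chosen = set(np.flatnonzero(sel).tolist())
    else:
        chosen = {int(i) for i in np.atleast_1d(sel)}
    if not chosen:
        return 0.0, (1.0 if not truth else 0.0)
    fdp = len(chosen - truth) / len(chosen)
    union = chosen | truth
    jaccard = len(chosen & truth) / len(union) if union else 1.0
    return fdp, jaccard


def direction_calls(
    signed_stats: StudyMatrix,
    p: StudyMatrix,
    p_cut: float = 0.01,
    ratio: float = 3.0,
):
    """Label each gene up / down / mixed from signed statistics.

    Events are the studies with p <= ``p_cut``; a gene is "up" when the
    up/down event ratio is >= ``ratio``, "down" when <= 1/ratio, otherwise
    "mixed".  A zero denominator counts as an infinite ratio; genes with no
    events at all are labelled mixed with a warning.
    """
    if signed_stats.values.shape != p.values.shape:
        raise ValueError("statistic and p-value matrices must be aligned")
    events = p.values <= p_cut
    up = ((signed_stats.values > 0) & events).sum(axis=1)
    down = ((signed_stats.values < 0) & events).sum(axis=1)
    labels = []
    none_count = 0
    for u, d in zip(up, down):
        if u + d == 0:
            labels.append("mixed")
            none_count += 1
            continue
        up_ratio = np.inf if d == 0 else u / d
        if up_ratio >= ratio:
            labels.append("up")
        elif up_ratio <= 1.0 / ratio:
            labels.append("down")
        else:
            labels.append("mixed")
    if none_count:
        warnings.warn(
            f"{none_count} gene(s) have no study passing p <= {p_cut}; "
            "labelled mixed"
        )
    return labels


def rank_vs_fisher(fdr_values, fisher_combined_p) -> float:
    """Spearman correlation between an fdr-based gene ranking and the
    Fisher combined-p ranking (average ranks on ties)."""
    fdr_values = np.asarray(fdr_values, dtype=float)
    fisher_combined_p = np.asarray(fisher_combined_p, dtype=float)
    if fdr_values.shape != fisher_combined_p.shape:
        raise ValueError("rankings must cover the same gene universe")
    rho, _ = stats.spearmanr(fdr_values, fisher_combined_p)
    return float(rho)
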
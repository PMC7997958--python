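"""Shared evaluation statistics for the simulation benchmarks.

Benjamini-Hochberg q-values, rank-based AUC, true-positive rate, the
realized ("true") false discovery rate among q-significant features, and
the hypergeometric enrichment p-value / odds ratio used to score overlap
with a gold-standard gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .types import InvalidInputError

__all__ = [
    "EvalMetrics",
    "EnrichmentResult",
    "bh_qvalues",
    "auc_score",
    "tpr_truefdr",
    "hypergeom_enrichment",
    "MIN_SIGNIFICANT_FOR_FDR",
]

#: The realized FDR is reported only when at least this many features
#: are significant; with fewer the ratio is too unstable to interpret.
MIN_SIGNIFICANT_FOR_FDR = 5


@dataclass
class EvalMetrics:
    """AUC / TPR / realized-FDR container for one method in one scenario.

    ``true_fdr`` is None when fewer than MIN_SIGNIFICANT_FOR_FDR features
    were significant; ``auc`` is None when the truth has a single class.
    """

    auc: Optional[float] = None
    tpr: Optional[float] = None
    true_fdr: Optional[float] = None
    n_significant: int = 0


@dataclass
class EnrichmentResult:
    N: int
    G: int
    D: int
    O: int
    p_enrich: float
    odds_ratio: float


def bh_qvalues(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidInputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def auc_score(scores: Sequence[float], truth: Sequence[bool]) -> Optional[float]:
    """Rank-based AUC: P(a random positive outranks a random negative), ties split.

    Returns None when the truth labels contain a single class.
    """
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if truth.all() or not truth.any():
        return None
    return float(roc_auc_score(truth, scores))


def tpr_truefdr(
    q: Sequence[float], truth: Sequence[bool], cutoff: float = 0.05
) -> EvalMetrics:
    """TPR and realized FDR of the q < cutoff significant set."""
    q = np.asarray(q, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if q.size != truth.size:
        raise InvalidInputError("q and truth must have equal length")
    sig = q < cutoff
    n_sig = int(sig.sum())
    tpr = float((sig & truth).sum() / truth.sum()) if truth.any() else None
    true_fdr = (
        float((sig & ~truth).sum() / n_sig)
        if n_sig >= MIN_SIGNIFICANT_FOR_FDR
        else None
    )
    return EvalMetrics(tpr=tpr, true_fdr=true_fdr, n_significant=n_sig)


def hypergeom_enrichment(N: int, G: int, D: int, O: int) -> EnrichmentResult:
    """Hypergeometric enrichment of a gold-standard set in a significant set.

    p = 1 - sum_{i=0}^{O-1} C(G,i) C(N-G, D-i) / C(N,D), the probability
    of an overlap of at least O by chance; the odds ratio is the
    proportion ratio (O/D) / (G/N).
    """
    for name, v in (("N", N), ("G", G), ("D", D), ("O", O)):
        if v < 0 or v != int(v):
            raise InvalidInputError(f"{name} must be a non-negative integer")
    if G > N or D > N or O > min(G, D):
        raise InvalidInputError("inconsistent counts: need O <= min(G, D) and G, D <= N")
    p = float(stats.hypergeom.sf(O - 1, N, G, D))
    odds_ratio = float((O / D) / (G / N)) if D > 0 and G > 0 else np.nan
    return EnrichmentResult(N=N, G=G, D=D, O=O, p_enrich=min(p, 1.0), odds_ratio=odds_ratio)
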
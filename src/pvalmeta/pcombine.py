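"""Classical and sample-size-weighted p-value combiners.

Implements Fisher's chi-square method, Stouffer's Z, the sample-size
weighted Z-method, Lancaster's chi-square generalisation (DF_i = s_i by
default), and wFisher — a gamma-quantile generalisation of Fisher's
method in which study i consumes shape k_i = n * s_i / S (scale 2) so
weights are proportional to sample size while the total degrees of
freedom stay at 2n, the same as unweighted Fisher.  Keeping the per-study
distributions right-skewed (small DFs) is what preserves power when many
of the combined studies are unassociated.

Conventions: every transform maps a p-value to the *upper-tail* quantile
of its reference distribution (the value whose survival probability is
p), and the combined p-value is the upper-tail probability of the summed
statistic.  Under equal sample sizes wFisher is then exactly Fisher and
the weighted Z exactly Stouffer.

The directional wrapper integrates two-tailed p-values with known effect
directions by halving and synchronising them (p/2 along the direction,
1 - p/2 against it), combining both the synchronised vector and its
complement, and doubling the smaller result.
"""

from __future__ import annotations

import warnings
from typing import Callable, Optional

import numpy as np
from mpmath import mp
from scipy import special, stats

from .types import CombinedResult, InvalidInputError, StudyEvidence, WeightScheme

__all__ = [
    "fisher_combine",
    "stouffer_combine",
    "weighted_z_combine",
    "lancaster_combine",
    "wfisher_combine",
    "combine_directional",
]

#: Floor for wFisher gamma shapes; below this the quantile transform is
#: numerically meaningless (the study carries ~zero weight anyway).
K_FLOOR = 1e-6


def _gamma_logsf(y: float, shape: float) -> float:
    """log of the regularized upper gamma tail Q(shape, y), mpmath fallback."""
    with np.errstate(under="ignore"):
        q = special.gammaincc(shape, y)
    if q > 1e-280:
        return float(np.log(q))
    with mp.workdps(50):
        val = mp.gammainc(shape, a=y, regularized=True)
        return float(mp.log(val)) if val > 0 else -np.inf


def _finish_tail(logp: float, method: str, statistic: float,
                 df_total: Optional[float]) -> CombinedResult:
    p = float(np.exp(logp)) if logp > -745.0 else 0.0
    extras = {}
    if logp < -600.0:
        extras["log10_p"] = logp / np.log(10.0)
    return CombinedResult(
        method=method,
        p_combined=min(p, 1.0),
        statistic=statistic,
        df_total=df_total,
        extras=extras,
    )


# ---------------------------------------------------------------------------
# individual combiners
# ---------------------------------------------------------------------------

def fisher_combine(ev: StudyEvidence) -> CombinedResult:
    """Fisher's method: T = -2 sum log p_i ~ chi-square(2n) under the null."""
    p = ev.p
    n = p.size
    T = float(-2.0 * np.log(p).sum())
    logp = _gamma_logsf(T / 2.0, n)
    return _finish_tail(logp, "fisher", T, 2.0 * n)


def stouffer_combine(ev: StudyEvidence) -> CombinedResult:
    """Stouffer's Z-method: Z = sum Phi^{-1}(1 - p_i) / sqrt(n)."""
    p = ev.p
    n = p.size
    z = special.ndtri(1.0 - p)
    # ndtri(1-p) loses accuracy for tiny p; isf is the stable route
    small = p < 1e-8
    if small.any():
        z[small] = -special.ndtri(p[small])
    Z = float(z.sum() / np.sqrt(n))
    logp = float(special.log_ndtr(-Z))
    return _finish_tail(logp, "stouffer", Z, None)


def weighted_z_combine(
    ev: StudyEvidence, weights: Optional[np.ndarray] = None
) -> CombinedResult:
    """Sample-size weighted Z: Z = sum w_i z_i / sqrt(sum w_i^2), w_i = sqrt(s_i)."""
    p = ev.p
    if weights is None:
        if ev.n is None:
            raise InvalidInputError(
                "weighted Z requires per-study sample sizes (or explicit weights)"
            )
        weights = WeightScheme.from_sample_sizes(ev.n).z_weights
    w = np.asarray(weights, dtype=float)
    if w.size != p.size or np.any(w <= 0):
        raise InvalidInputError("weights must be positive, one per study")
    z = -special.ndtri(p)
    Z = float((w * z).sum() / np.sqrt((w**2).sum()))
    logp = float(special.log_ndtr(-Z))
    return _finish_tail(logp, "weighted_z", Z, None)


def lancaster_combine(
    ev: StudyEvidence, df: Optional[np.ndarray] = None
) -> CombinedResult:
    """Lancaster's method: p_i -> upper chi-square(s_i) quantile, sum ~ chi-square(S)."""
    p = ev.p
    if df is None:
        if ev.n is None:
            raise InvalidInputError(
                "Lancaster's method requires per-study sample sizes as degrees of freedom"
            )
        df = ev.n
    df = np.asarray(df, dtype=float)
    if df.size != p.size or np.any(df <= 0):
        raise InvalidInputError("degrees of freedom must be positive, one per study")
    # chi-square(df) == gamma(df/2, scale 2); non-integer DFs take the
    # same gamma route rather than being rounded
    with np.errstate(under="ignore"):
        L = float(2.0 * special.gammainccinv(df / 2.0, p).sum())
    S = float(df.sum())
    logp = _gamma_logsf(L / 2.0, S / 2.0)
    return _finish_tail(logp, "lancaster", L, S)


def wfisher_combine(
    ev: StudyEvidence, k: Optional[np.ndarray] = None, k_floor: float = K_FLOOR
) -> CombinedResult:
    """Sample-size weighted Fisher: gamma(k_i, 2) quantiles, sum ~ chi-square(2n).

    k_i = n * s_i / S keeps sum k_i = n, so the combined statistic has
    the same chi-square(2n) reference as unweighted Fisher while studies
    with larger samples consume proportionally more of it.
    """
    p = ev.p
    n = p.size
    if k is None:
        if ev.n is None:
            raise InvalidInputError("wFisher requires per-study sample sizes")
        k = WeightScheme.from_sample_sizes(ev.n).k
    k = np.asarray(k, dtype=float)
    if k.size != p.size or np.any(k <= 0):
        raise InvalidInputError("gamma shapes must be positive, one per study")
    if np.any(k < k_floor):
        warnings.warn(
            f"wFisher gamma shape below {k_floor:g} clamped (near-zero study weight)",
            RuntimeWarning,
            stacklevel=2,
        )
        k = np.maximum(k, k_floor)
    with np.errstate(under="ignore"):
        x = 2.0 * special.gammainccinv(k, p)
    X = float(x.sum())
    logp = _gamma_logsf(X / 2.0, n)
    return _finish_tail(logp, "wfisher", X, 2.0 * n)


# ---------------------------------------------------------------------------
# directional (two-tailed) integration
# ---------------------------------------------------------------------------

def combine_directional(
    ev: StudyEvidence,
    method: "str | Callable[[StudyEvidence], CombinedResult]",
    one_tailed: bool = False,
    **params,
) -> CombinedResult:
    """Integrate two-tailed p-values with known effect directions.

    Builds the synchronised one-tailed vector u_i = p_i/2 for sign +1
    and 1 - p_i/2 for sign -1, combines it and its elementwise
    complement with the requested method, and returns twice the smaller
    of the two combined p-values (capped at 1).  ``direction`` records
    which side won.

    With ``one_tailed=True`` the inputs are taken as already halved and
    synchronised (u_i = p_i for sign +1, 1 - p_i for sign -1), as in
    published association tables that print synchronised cohort
    p-values; only the two-sided combine-both-directions-and-double step
    is applied.
    """
    from .registry import get_combiner  # local import to avoid a cycle

    if ev.sign is None:
        raise InvalidInputError("directional combination requires effect signs")
    fn = get_combiner(method) if isinstance(method, str) else method
    if one_tailed:
        u = np.where(ev.sign > 0, ev.p, 1.0 - ev.p)
    else:
        u = np.where(ev.sign > 0, ev.p / 2.0, 1.0 - ev.p / 2.0)
    results = []
    for vec in (u, 1.0 - u):
        sub = StudyEvidence(p=vec, n=None if ev.n is None else ev.n.copy(),
                            feature_id=ev.feature_id)
        results.append(fn(sub, **params))
    up, down = results
    direction = 1 if up.p_combined <= down.p_combined else -1
    winner = up if direction == 1 else down
    extras = dict(winner.extras)
    if "log10_p" in extras:
        extras["log10_p"] += np.log10(2.0)
    return CombinedResult(
        method=winner.method,
        p_combined=min(1.0, 2.0 * winner.p_combined),
        statistic=winner.statistic,
        df_total=winner.df_total,
        direction=direction,
        extras=extras,
    )


# ---------------------------------------------------------------------------
# vectorised bulk paths (simulation experiments)
# ---------------------------------------------------------------------------

def fisher_pvalues_batch(P: np.ndarray) -> np.ndarray:
    """Fisher combined p-values, one per row."""
    n = P.shape[1]
    T = -2.0 * np.log(P).sum(axis=1)
    return stats.chi2.sf(T, 2 * n)


def stouffer_pvalues_batch(P: np.ndarray) -> np.ndarray:
    n = P.shape[1]
    Z = (-special.ndtri(P)).sum(axis=1) / np.sqrt(n)
    return special.ndtr(-Z)


def _as_size_matrix(sizes: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    s = np.asarray(sizes, dtype=float)
    if s.ndim == 1:
        s = np.broadcast_to(s[None, :], shape)
    if s.shape != shape:
        raise InvalidInputError("sizes must be (n,) or match the p-value matrix")
    return s


def weighted_z_pvalues_batch(P: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    w = np.sqrt(_as_size_matrix(sizes, P.shape))
    Z = (w * (-special.ndtri(P))).sum(axis=1) / np.sqrt((w**2).sum(axis=1))
    return special.ndtr(-Z)


def lancaster_pvalues_batch(P: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    df = _as_size_matrix(sizes, P.shape)
    L = 2.0 * special.gammainccinv(df / 2.0, P).sum(axis=1)
    return special.gammaincc(df.sum(axis=1) / 2.0, L / 2.0)


def wfisher_pvalues_batch(P: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    n = P.shape[1]
    s = _as_size_matrix(sizes, P.shape)
    k = n * s / s.sum(axis=1, keepdims=True)
    X = special.gammainccinv(k, P).sum(axis=1)
    return special.gammaincc(float(n), X)
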
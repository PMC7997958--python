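"""Order-statistic machinery for combining p-values.

For n i.i.d. Uniform(0,1) p-values, the r-th smallest follows a
Beta(r, n-r+1) marginal.  The r-th ordered p-value (roP) method tests a
single fixed rank's marginal probability F_(r)(p_(r)); ordmeta instead
takes the minimum marginal over all ranks,

    X = min_r F_(r)(p_(r)),

and evaluates its exact null probability P(X <= alpha) under the joint
distribution of uniform order statistics.  That probability equals the
chance that the vector of order statistics crosses the rank-wise
boundary c_r = F_(r)^{-1}(alpha) somewhere, i.e.
P(exists r: p_(r) <= c_r), which this module computes two ways:

* a first-crossing recursion (Steck-type) carried out in arbitrary
  precision, exact for arbitrarily small combined p-values; and
* a cancellation-free double-precision recursion over the counts of
  uniforms falling in successive boundary intervals, used in bulk
  simulation where the combined p is moderate.

Because ordmeta conditions only on the minimum marginal, input p-values
larger than the optimal order statistic cannot influence the result —
the property that makes it robust to unassociated (null) studies.  The
ranks at or below the optimal order are reported as the studies
predicted to carry a true effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np
from mpmath import mp
from scipy import special

from .types import CombinedResult, InvalidInputError, StudyEvidence

__all__ = [
    "OrderBoundVector",
    "OrdmetaResult",
    "marginal_order_p",
    "log_marginal_order_p",
    "rop_combine",
    "order_bounds",
    "joint_survival",
    "ordmeta_combine",
    "ordmeta_pvalues_batch",
    "predict_associated",
]

# Above this study count double factorials overflow; everything routes
# through the arbitrary-precision path.
_MAX_DOUBLE_N = 140


# ---------------------------------------------------------------------------
# Beta marginals of ordered uniforms
# ---------------------------------------------------------------------------

def log_marginal_order_p(r: int, n: int, x: float) -> float:
    """log F_(r)(x) for the r-th of n ordered uniforms, log-space exact.

    Uses the binomial-tail identity F_(r)(x) = P(Bin(n, x) >= r), summed
    with logsumexp, so the result keeps full relative accuracy down to
    x ~ 1e-300 where the regularized incomplete beta underflows.
    """
    _check_rank(r, n)
    if x <= 0.0:
        return -np.inf
    if x >= 1.0:
        return 0.0
    j = np.arange(r, n + 1, dtype=float)
    logterms = (
        special.gammaln(n + 1)
        - special.gammaln(j + 1)
        - special.gammaln(n - j + 1)
        + j * np.log(x)
        + (n - j) * np.log1p(-x)
    )
    return float(special.logsumexp(logterms))


def marginal_order_p(r: int, n: int, x: float) -> float:
    """F_(r)(x) = I_x(r, n-r+1): Beta(r, n-r+1) CDF of the r-th order statistic."""
    return float(np.exp(log_marginal_order_p(r, n, x)))


def _log_marginals_sorted(p_sorted: np.ndarray) -> np.ndarray:
    """log F_(r)(p_(r)) for every rank r of an ascending p-value vector."""
    n = p_sorted.size
    j = np.arange(1, n + 1, dtype=float)
    logbin = (
        special.gammaln(n + 1) - special.gammaln(j + 1) - special.gammaln(n - j + 1)
    )
    logx = np.log(p_sorted)
    log1mx = np.log1p(-p_sorted)
    # terms[r-1, j-1] = log C(n,j) + j log p_(r) + (n-j) log(1-p_(r)), j >= r
    terms = logbin[None, :] + j[None, :] * logx[:, None] + (n - j)[None, :] * log1mx[:, None]
    terms = np.where(j[None, :] >= j[:, None], terms, -np.inf)
    return special.logsumexp(terms, axis=1)


def _check_rank(r: int, n: int) -> None:
    if not (isinstance(r, (int, np.integer)) and 1 <= r <= n):
        raise InvalidInputError(f"rank r={r} outside 1..{n}")


# ---------------------------------------------------------------------------
# Rank-wise boundary inversion
# ---------------------------------------------------------------------------

@dataclass
class OrderBoundVector:
    """Rank-wise thresholds c_r = F_(r)^{-1}(alpha), non-decreasing in r."""

    alpha: float
    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if np.any(np.diff(self.c) < -1e-12):
            raise InvalidInputError("order bounds must be non-decreasing")

    @property
    def n(self) -> int:
        return int(self.c.size)


def _solve_bound_log(r: int, n: int, log_alpha: float) -> float:
    """log c solving F_(r)(c) = alpha, by safeguarded Newton on log c.

    Seeded with the small-x asymptote c ~ (alpha * r * B(r, n-r+1))^{1/r};
    g(u) = log F_(r)(e^u) - log alpha is increasing in u, so Newton steps
    are bracketed by bisection against (-inf, 0).
    """
    if log_alpha == -np.inf:
        return -np.inf
    if log_alpha >= 0.0:
        return 0.0
    logB = special.betaln(r, n - r + 1)
    u = (log_alpha + np.log(r) + logB) / r
    u = min(u, -1e-17)
    lo, hi = None, 0.0  # bracket on u
    for _ in range(100):
        c = np.exp(u)
        g = log_marginal_order_p(r, n, c) - log_alpha
        if abs(g) < 1e-13:
            break
        if g > 0:
            hi = u
        else:
            lo = u
        # d/du log F = c f(c) / F(c)
        logf = -logB + (r - 1) * u + (n - r) * np.log1p(-c)
        logF = g + log_alpha
        slope = np.exp(u + logf - logF)
        if slope <= 0 or not np.isfinite(slope):
            step = None
        else:
            step = g / slope
        u_new = u - step if step is not None else None
        if (
            u_new is None
            or not np.isfinite(u_new)
            or u_new >= 0.0
            or (lo is not None and u_new <= lo)
            or (u_new >= hi and g > 0)
        ):
            # bisect within the current bracket
            if lo is None:
                u_new = u - 1.0 if g > 0 else (u + hi) / 2.0
            else:
                u_new = (lo + hi) / 2.0
        if u_new == u:
            break
        u = u_new
    return float(u)


def order_bounds(alpha: float, n: int) -> OrderBoundVector:
    """Invert every rank's marginal: c_r with F_(r)(c_r) = alpha.

    Relative accuracy of each bound is ~1e-12, maintained for alpha far
    below double underflow of the naive beta inverse.
    """
    if not (0.0 <= alpha <= 1.0):
        raise InvalidInputError("alpha must lie in [0, 1]")
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if alpha == 0.0:
        return OrderBoundVector(alpha, np.zeros(n))
    if alpha == 1.0:
        return OrderBoundVector(alpha, np.ones(n))
    log_alpha = float(np.log(alpha))
    c = np.array([np.exp(_solve_bound_log(r, n, log_alpha)) for r in range(1, n + 1)])
    c = np.maximum.accumulate(c)  # enforce monotonicity against rounding
    return OrderBoundVector(alpha, c)


def _log_order_bounds(log_alpha: float, n: int) -> np.ndarray:
    return np.array([_solve_bound_log(r, n, log_alpha) for r in range(1, n + 1)])


# ---------------------------------------------------------------------------
# Joint survival / boundary crossing of ordered uniforms
# ---------------------------------------------------------------------------

def _survival_double(c: np.ndarray) -> float:
    """P(p_(1) > c_1, ..., p_(n) > c_n) by a positive-term recursion.

    Conditions on the counts of uniforms falling in successive intervals
    (c_{j-1}, c_j]: the survival event is {N_j <= j-1 for all j} where
    N_j counts points at or below c_j.  Every term in the recursion is
    non-negative, so double precision keeps near-machine relative
    accuracy for the survival probability itself (the complement 1 - S
    is only trustworthy down to ~1e-12).
    """
    c = np.asarray(c, dtype=float)
    n = c.size
    if n > _MAX_DOUBLE_N:
        raise InvalidInputError(f"double-precision path limited to n <= {_MAX_DOUBLE_N}")
    if c[-1] >= 1.0:
        return 0.0
    fact = special.factorial(np.arange(n + 1), exact=False)
    g = np.array([1.0])
    cprev = 0.0
    for jj in range(1, n + 1):
        cj = c[jj - 1]
        rho = (cj - cprev) / (1.0 - cprev)
        if rho < 0.0:
            raise InvalidInputError("order bounds must be non-decreasing")
        m = np.arange(jj)
        a = g * fact[n - np.arange(g.size)]
        b = rho ** np.arange(jj, dtype=float) / fact[:jj]
        conv = np.convolve(a, b)[:jj]
        g = conv * (1.0 - rho) ** (n - m) / fact[n - m]
        cprev = cj
    return float(g.sum())


def _crossing_mp_once(logc: np.ndarray, n: int, dps: int):
    """First-crossing probability at fixed precision (Steck recursion).

    h_r = c_r^r - sum_{j<r} C(r,j) h_j (c_r - c_j)^{r-j};
    P(crossing) = sum_r C(n,r) h_r (1 - c_r)^{n-r}.
    """
    with mp.workdps(dps):
        c = [mp.e ** mp.mpf(float(v)) if np.isfinite(v) else mp.mpf(0) for v in logc]
        h = [mp.mpf(0)] * (n + 1)
        for r in range(1, n + 1):
            acc = c[r - 1] ** r
            for j in range(1, r):
                acc -= mp.binomial(r, j) * h[j] * (c[r - 1] - c[j - 1]) ** (r - j)
            h[r] = acc
        total = mp.mpf(0)
        for r in range(1, n + 1):
            total += mp.binomial(n, r) * h[r] * (1 - c[r - 1]) ** (n - r)
        return +total


def _crossing_mp(logc: np.ndarray, n: int):
    """Adaptive-precision first-crossing probability (mpmath scalar)."""
    dps = max(50, 30 + 2 * n)
    prev = _crossing_mp_once(logc, n, dps)
    for _ in range(4):
        dps *= 2
        cur = _crossing_mp_once(logc, n, dps)
        if prev != 0 and mp.fabs(cur - prev) <= mp.fabs(cur) * mp.mpf(10) ** (-13):
            return cur
        prev = cur
    return prev


def joint_survival(bounds: "OrderBoundVector | Sequence[float]") -> float:
    """P(p_(1) > c_1, ..., p_(n) > c_n) for n i.i.d. uniforms.

    The complement 1 - P is computed cancellation-safely: when it falls
    below ~1e-6 the arbitrary-precision crossing recursion takes over,
    so the complement keeps <= 1e-6 relative error down to 1e-300.
    """
    c = bounds.c if isinstance(bounds, OrderBoundVector) else np.asarray(bounds, float)
    if np.any(np.diff(c) < -1e-12):
        raise InvalidInputError("order bounds must be non-decreasing")
    if np.any((c < 0) | (c > 1)):
        raise InvalidInputError("order bounds must lie in [0, 1]")
    c = np.maximum.accumulate(np.clip(c, 0.0, 1.0))
    n = c.size
    if c[-1] >= 1.0:
        return 0.0
    if c[-1] == 0.0:
        return 1.0
    if n <= _MAX_DOUBLE_N:
        S = _survival_double(c)
        if np.isfinite(S) and 0.0 <= S <= 1.0 and (1.0 - S) >= 1e-6:
            return S
    with np.errstate(divide="ignore"):
        logc = np.log(c)
    cross = _crossing_mp(logc, n)
    return float(1 - cross)


# ---------------------------------------------------------------------------
# ordmeta
# ---------------------------------------------------------------------------

@dataclass
class OrdmetaResult:
    """Result of the minimum-marginal order-statistic combination.

    ``min_marginal`` is X = min_r F_(r)(p_(r)); ``optimal_order`` the
    arg-min rank r* (smallest rank on ties); ``predicted_mask`` flags, in
    the original study order, the r* smallest p-values — the studies the
    method predicts to carry a true effect.  ``extras['p_str']`` holds a
    high-precision decimal of the combined p when it approaches or falls
    below double-precision underflow.
    """

    p_combined: float
    min_marginal: float
    optimal_order: int
    predicted_mask: np.ndarray
    log_min_marginal: float = np.nan
    extras: dict[str, Any] = field(default_factory=dict)


def ordmeta_combine(ev: StudyEvidence) -> OrdmetaResult:
    """Combine one-tailed p-values by the minimum marginal of ordered uniforms.

    Computes X = min_r F_(r)(p_(r)) and its exact null probability
    P(X <= alpha) = P(exists r: p_(r) <= F_(r)^{-1}(alpha)) under the
    joint distribution of uniform order statistics.
    """
    p = ev.p
    n = p.size
    order = np.argsort(p, kind="stable")
    p_sorted = p[order]
    logF = _log_marginals_sorted(p_sorted)
    rstar = int(np.argmin(logF))  # first minimum: smallest rank wins ties
    logX = float(logF[rstar])
    X = float(np.exp(logX))
    extras: dict[str, Any] = {}

    if n == 1:
        p_comb = float(p_sorted[0])
    else:
        p_comb = None
        if X > 1e-10 and n <= _MAX_DOUBLE_N:
            c = order_bounds(X, n).c
            S = _survival_double(c)
            cand = 1.0 - S
            if np.isfinite(cand) and cand >= 1e-6:
                p_comb = cand
        if p_comb is None:
            logc = _log_order_bounds(logX, n)
            cross = _crossing_mp(logc, n)
            p_comb = float(cross)
            if p_comb < 1e-280:
                extras["p_str"] = mp.nstr(cross, 15)
        # exact inclusion-exclusion lies in [X, n*X]; guard float rounding
        p_comb = float(min(max(p_comb, X), min(1.0, n * X) if X > 0 else 1.0))

    mask = np.zeros(n, dtype=bool)
    mask[order[: rstar + 1]] = True
    return OrdmetaResult(
        p_combined=p_comb,
        min_marginal=X,
        optimal_order=rstar + 1,
        predicted_mask=mask,
        log_min_marginal=logX,
        extras=extras,
    )


def ordmeta_as_combined(ev: StudyEvidence) -> CombinedResult:
    """ordmeta in the shared CombinedResult container (registry adapter)."""
    res = ordmeta_combine(ev)
    extras = dict(res.extras)
    extras["optimal_order"] = res.optimal_order
    extras["predicted_mask"] = res.predicted_mask
    return CombinedResult(
        method="ordmeta",
        p_combined=res.p_combined,
        statistic=res.min_marginal,
        df_total=None,
        extras=extras,
    )


def predict_associated(ev: StudyEvidence) -> np.ndarray:
    """Flag the studies predicted to carry a true effect.

    The r* smallest p-values (r* the ordmeta optimal order) are returned
    as True in the original study order.  Only the marginals are needed,
    so the joint-survival evaluation is skipped.
    """
    order = np.argsort(ev.p, kind="stable")
    logF = _log_marginals_sorted(ev.p[order])
    rstar = int(np.argmin(logF))
    mask = np.zeros(ev.p.size, dtype=bool)
    mask[order[: rstar + 1]] = True
    return mask


def ordmeta_pvalues_batch(
    pmat: np.ndarray,
    exact_small: bool = True,
    small_threshold: float = 1e-6,
) -> np.ndarray:
    """Vectorised ordmeta combined p-values, one per row of ``pmat``.

    Bulk path for simulation experiments: beta-CDF marginals and the
    double-precision survival recursion per row.  Rows whose combined p
    falls below ``small_threshold`` (where 1 - S loses relative accuracy)
    are recomputed exactly when ``exact_small`` is set, otherwise clamped
    into the [X, nX] sandwich — sufficient when the values only feed a
    rejection count at a much larger cutoff.
    """
    P = np.asarray(pmat, dtype=float)
    if P.ndim != 2:
        raise InvalidInputError("pmat must be 2-D (replicates x studies)")
    reps, n = P.shape
    Ps = np.sort(P, axis=1)
    r = np.arange(1, n + 1, dtype=float)
    with np.errstate(under="ignore"):
        marg = special.betainc(r[None, :], (n - r + 1)[None, :], Ps)
    alpha = marg.min(axis=1)
    out = np.empty(reps)
    if n == 1:
        return Ps[:, 0].copy()
    with np.errstate(under="ignore"):
        C = special.betaincinv(r[None, :], (n - r + 1)[None, :], alpha[:, None])
    C = np.maximum.accumulate(C, axis=1)
    for i in range(reps):
        a = alpha[i]
        if a <= small_threshold / n:
            out[i] = -1.0  # forced escalation/clamp below
            continue
        S = _survival_double(C[i])
        out[i] = 1.0 - S
    bad = (~np.isfinite(out)) | (out < small_threshold)
    if exact_small and bad.any():
        for i in np.nonzero(bad)[0]:
            out[i] = ordmeta_combine(StudyEvidence(p=P[i])).p_combined
    else:
        lo = alpha
        hi = np.minimum(1.0, n * alpha)
        out = np.clip(out, lo, hi)
    return out


# ---------------------------------------------------------------------------
# roP
# ---------------------------------------------------------------------------

def rop_combine(ev: StudyEvidence, r: int) -> CombinedResult:
    """r-th ordered p-value method: the fixed rank's beta marginal.

    p_combined = F_(r)(p_(r)) with p_(r) the r-th smallest input; unlike
    ordmeta the rank is chosen a priori and no joint correction is needed.
    """
    p_sorted = np.sort(ev.p)
    n = p_sorted.size
    _check_rank(r, n)
    x = float(p_sorted[r - 1])
    p_comb = marginal_order_p(r, n, x)
    return CombinedResult(
        method="rop",
        p_combined=min(p_comb, 1.0),
        statistic=x,
        extras={"rank": int(r)},
    )
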
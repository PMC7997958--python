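"""Shared containers for per-feature study evidence and combiner output.

A meta-analysis over *n* independent studies is driven, per feature
(gene, variant, ...), by a vector of per-study p-values, optionally
accompanied by effect directions and per-study sample sizes.  These
containers normalise that input once (missing-value removal, endpoint
clamping) so every combiner sees the same sanitised evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Optional, Sequence

import numpy as np

__all__ = [
    "StudyEvidence",
    "CombinedResult",
    "WeightScheme",
    "EffectEvidence",
    "InvalidInputError",
    "P_FLOOR",
    "P_CEIL",
]

#: Clamp floor for p = 0 inputs: quantile transforms diverge at zero.
P_FLOOR = 1e-320
#: Clamp ceiling for p = 1 inputs: upper-tail quantiles diverge at one.
P_CEIL = 1.0 - 1e-16


class InvalidInputError(ValueError):
    """Raised when evidence violates a combiner's preconditions."""


def _clamp_pvalues(p: np.ndarray) -> np.ndarray:
    out = p.copy()
    low = out < P_FLOOR
    high = out > P_CEIL
    if low.any() or high.any():
        warnings.warn(
            "p-values at or beyond (0, 1] endpoints clamped to "
            f"[{P_FLOOR:g}, {P_CEIL!r}]",
            RuntimeWarning,
            stacklevel=3,
        )
    out[low] = P_FLOOR
    out[high] = P_CEIL
    return out


@dataclass
class StudyEvidence:
    """Per-study p-values for one feature, with optional signs and sizes.

    Parameters
    ----------
    p
        Per-study p-values.  Values outside ``(0, 1]`` after clamping are
        rejected; NaN marks a missing study and is dropped together with
        its sign / sample-size entries.
    sign
        Optional effect directions, one of {+1, -1} per study.  Required
        by the directional (two-tailed) wrapper.
    n
        Optional positive per-study sample sizes ``s_i``; required by the
        sample-size-weighted combiners.
    feature_id
        Opaque label carried through to results.
    """

    p: np.ndarray
    sign: Optional[np.ndarray] = None
    n: Optional[np.ndarray] = None
    feature_id: Optional[str] = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float).ravel()
        if p.size == 0:
            raise InvalidInputError("at least one p-value is required")
        sign = None if self.sign is None else np.asarray(self.sign, dtype=float).ravel()
        sizes = None if self.n is None else np.asarray(self.n, dtype=float).ravel()
        for name, arr in (("sign", sign), ("n", sizes)):
            if arr is not None and arr.size != p.size:
                raise InvalidInputError(
                    f"{name} has length {arr.size}, expected {p.size}"
                )
        keep = ~np.isnan(p)
        if sizes is not None:
            keep &= ~np.isnan(sizes)
        if not keep.any():
            raise InvalidInputError("all studies are missing")
        p = p[keep]
        if np.any((p < 0) | (p > 1)):
            raise InvalidInputError("p-values must lie in [0, 1]")
        self.p = _clamp_pvalues(p)
        if sign is not None:
            sign = sign[keep]
            if np.any(np.abs(sign) != 1):
                raise InvalidInputError("signs must be +1 or -1")
            self.sign = sign.astype(int)
        else:
            self.sign = None
        if sizes is not None:
            sizes = sizes[keep]
            if np.any(sizes <= 0):
                raise InvalidInputError("sample sizes must be positive")
            self.n = sizes
        else:
            self.n = None

    @property
    def n_studies(self) -> int:
        return int(self.p.size)

    @property
    def total_sample_size(self) -> float:
        """S = sum of retained per-study sample sizes."""
        if self.n is None:
            raise InvalidInputError("sample sizes are not available")
        return float(self.n.sum())


@dataclass
class CombinedResult:
    """Output of a p-value combiner.

    ``statistic`` is the method's test statistic (Fisher's T, Lancaster's
    L, the Z-sum, wFisher's gamma-sum, or ordmeta's minimum marginal);
    ``df_total`` the total degrees of freedom consumed where applicable
    (2n for Fisher/wFisher, S for Lancaster).  ``extras`` carries
    method-specific payload, e.g. ``optimal_order`` and
    ``predicted_mask`` for ordmeta, or ``p_str`` with a high-precision
    decimal string when the combined p underflows double precision.
    """

    method: str
    p_combined: float
    statistic: float
    df_total: Optional[float] = None
    direction: Optional[int] = None
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_combined <= 1.0):
            raise AssertionError(
                f"combined p-value {self.p_combined} outside [0, 1]"
            )


@dataclass
class WeightScheme:
    """Per-study weights for the weighted combiners.

    ``k`` are gamma shape parameters ``k_i = n * s_i / S`` (wFisher,
    summing to the retained study count), ``chisq_df`` chi-square degrees
    of freedom (Lancaster, default ``s_i``), ``z_weights`` weights for
    the weighted Z-method (default ``sqrt(s_i)``).
    """

    k: Optional[np.ndarray] = None
    chisq_df: Optional[np.ndarray] = None
    z_weights: Optional[np.ndarray] = None

    @classmethod
    def from_sample_sizes(cls, sizes: Sequence[float]) -> "WeightScheme":
        s = np.asarray(sizes, dtype=float)
        if np.any(s <= 0):
            raise InvalidInputError("sample sizes must be positive")
        n = s.size
        return cls(k=n * s / s.sum(), chisq_df=s.copy(), z_weights=np.sqrt(s))


@dataclass
class EffectEvidence:
    """Per-study effect estimates and standard errors for one feature."""

    beta: np.ndarray
    se: np.ndarray
    feature_id: Optional[str] = None

    def __post_init__(self) -> None:
        beta = np.asarray(self.beta, dtype=float).ravel()
        se = np.asarray(self.se, dtype=float).ravel()
        if beta.size == 0:
            raise InvalidInputError("at least one study is required")
        if beta.size != se.size:
            raise InvalidInputError("beta and se must have equal length")
        keep = ~(np.isnan(beta) | np.isnan(se))
        if not keep.any():
            raise InvalidInputError("all studies are missing")
        beta, se = beta[keep], se[keep]
        if np.any(se <= 0):
            raise InvalidInputError("standard errors must be positive")
        self.beta, self.se = beta, se

    @property
    def n_studies(self) -> int:
        return int(self.beta.size)
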
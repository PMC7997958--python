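"""Minimal effect-size meta-analysis baselines.

Fixed-effects inverse-variance pooling and the DerSimonian-Laird
random-effects model.  These exist as comparison baselines for the
simulation benchmarks, not as a full effect-size meta-analysis toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from .types import EffectEvidence, InvalidInputError

__all__ = ["EffectMetaResult", "fixed_effect_meta", "random_effect_meta"]


@dataclass
class EffectMetaResult:
    method: str
    beta: float
    se: float
    p_value: float
    tau2: float = 0.0

    @property
    def z(self) -> float:
        return self.beta / self.se


def _two_tailed_p(beta: float, se: float) -> float:
    return float(2.0 * special.ndtr(-abs(beta / se)))


def fixed_effect_meta(ev: EffectEvidence) -> EffectMetaResult:
    """Inverse-variance pooled estimate: w_i = 1/se_i^2."""
    w = 1.0 / ev.se**2
    beta = float((w * ev.beta).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    return EffectMetaResult("fem", beta, se, _two_tailed_p(beta, se))


def random_effect_meta(ev: EffectEvidence) -> EffectMetaResult:
    """DerSimonian-Laird random effects.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) from
    Cochran's Q, then inverse-variance pooling with w_i* = 1/(se_i^2 + tau^2).
    """
    k = ev.n_studies
    if k < 2:
        raise InvalidInputError("random-effects pooling requires at least 2 studies")
    w = 1.0 / ev.se**2
    beta_fe = (w * ev.beta).sum() / w.sum()
    Q = float((w * (ev.beta - beta_fe) ** 2).sum())
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (ev.se**2 + tau2)
    beta = float((w_star * ev.beta).sum() / w_star.sum())
    se = float(1.0 / np.sqrt(w_star.sum()))
    res = EffectMetaResult("rem", beta, se, _two_tailed_p(beta, se), tau2=tau2)
    return res
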
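"""Method registry shared by the library API and the CLI."""

from __future__ import annotations

from typing import Callable, Dict

from .types import CombinedResult, InvalidInputError, StudyEvidence
from . import ordstat, pcombine

__all__ = ["COMBINERS", "get_combiner", "combine", "method_tags"]

#: Tag -> combiner callable taking a StudyEvidence (plus method kwargs).
COMBINERS: Dict[str, Callable[..., CombinedResult]] = {
    "fisher": pcombine.fisher_combine,
    "stouffer": pcombine.stouffer_combine,
    "wz": pcombine.weighted_z_combine,
    "lancaster": pcombine.lancaster_combine,
    "wfisher": pcombine.wfisher_combine,
    "ordmeta": ordstat.ordmeta_as_combined,
    "rop": ordstat.rop_combine,
}


def method_tags() -> list[str]:
    return sorted(COMBINERS)


def get_combiner(tag: str) -> Callable[..., CombinedResult]:
    try:
        return COMBINERS[tag]
    except KeyError:
        raise InvalidInputError(
            f"unknown method {tag!r}; registered: {', '.join(method_tags())}"
        ) from None


def combine(
    ev: StudyEvidence, method: str, directional: bool = False, **params
) -> CombinedResult:
    """Dispatch a combination by method tag.

    With ``directional=True`` the two-tailed halve/synchronise/double
    wrapper is applied (requires effect signs on the evidence).
    """
    if directional:
        return pcombine.combine_directional(ev, method, **params)
    return get_combiner(method)(ev, **params)
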
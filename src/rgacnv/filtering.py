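"""Call-level quality and assembly-gap filters for read-depth CNV calls.

Two filters are applied to raw CNVnator-style calls before any gene
association:

* a quality filter removing calls whose e-value or q0 (fraction of
  zero-mapping-quality reads) is at or above its threshold — either
  criterion alone flags an unreliable call;
* a gap filter removing calls that reciprocally overlap an assembly N-gap
  by at least ``gap_frac`` of both the call and the gap (bedtools
  ``intersect -f 0.50 -r -v`` semantics, evaluated per gap feature).

Both boundaries are inclusive (a call with e-value exactly at the threshold
is removed; a 50%/50% reciprocal gap overlap removes the call).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .io import CnvCall, GapTrack
from .intervals import overlap_fractions

logger = logging.getLogger(__name__)

__all__ = ["FilterConfig", "FilterResult", "quality_filter", "gap_filter"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the quality and gap filters.

    e_max : calls with e-value ≥ this are removed (default 0.05).
    q0_max : calls with q0 ≥ this are removed (default 0.5).
    gap_frac : minimum overlap fraction with a gap feature (default 0.50).
    gap_reciprocal : require the fraction on both call and gap (default True).
    """

    e_max: float = 0.05
    q0_max: float = 0.5
    gap_frac: float = 0.50
    gap_reciprocal: bool = True

    def __post_init__(self) -> None:
        for name in ("e_max", "q0_max", "gap_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")


class FilterResult(NamedTuple):
    kept: list[CnvCall]
    removed: list[tuple[CnvCall, str]]


def quality_filter(calls: Sequence[CnvCall], cfg: FilterConfig | None = None) -> FilterResult:
    """Remove calls failing the e-value OR the q0 criterion.

    A call is removed iff ``e_value >= e_max`` or ``q0 >= q0_max``. A q0 of
    −1 (CNVnator's no-reads sentinel) encodes absence of evidence rather
    than mapping ambiguity; such calls are kept by the q0 criterion and
    flagged in the log. Input order is preserved in both outputs.
    """
    cfg = cfg or FilterConfig()
    kept: list[CnvCall] = []
    removed: list[tuple[CnvCall, str]] = []
    for call in calls:
        reasons = []
        if call.e_value >= cfg.e_max:
            reasons.append(f"e_value {call.e_value!r} >= {cfg.e_max}")
        if call.q0 == -1.0:
            logger.debug("call %s has missing q0 (-1); q0 criterion skipped", call.call_id)
        elif call.q0 >= cfg.q0_max:
            reasons.append(f"q0 {call.q0!r} >= {cfg.q0_max}")
        if reasons:
            removed.append((call, "; ".join(reasons)))
        else:
            kept.append(call)
    return FilterResult(kept, removed)


def gap_filter(
    calls: Sequence[CnvCall], gaps: GapTrack, cfg: FilterConfig | None = None
) -> FilterResult:
    """Remove calls reciprocally overlapping an assembly gap.

    With ``gap_reciprocal`` a call is removed iff some single gap interval
    covers ≥ ``gap_frac`` of the call AND the call covers ≥ ``gap_frac`` of
    that gap; without it only the fraction of the call is required. The test
    is per gap feature, never against the union of gaps.
    """
    cfg = cfg or FilterConfig()
    kept: list[CnvCall] = []
    removed: list[tuple[CnvCall, str]] = []
    for call in calls:
        hit = None
        for gap in gaps.overlapping(call.interval):
            f_call, f_gap = overlap_fractions(call.interval, gap)
            if f_call >= cfg.gap_frac and (not cfg.gap_reciprocal or f_gap >= cfg.gap_frac):
                hit = (gap, f_call, f_gap)
                break
        if hit is not None:
            gap, f_call, f_gap = hit
            removed.append(
                (call, f"gap {gap} overlap {f_call:.3f} of call, {f_gap:.3f} of gap")
            )
        else:
            kept.append(call)
    return FilterResult(kept, removed)
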
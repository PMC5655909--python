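"""Pre-consensus call filters.

Four rules are applied per call, in a fixed order so that the removal
accounting is deterministic (each call is charged to the first rule it
fails):

1. gap-breakpoint — a breakpoint lies within ``window`` bp of an assembly
   gap;
2. gap-fraction — strictly more than ``max_gap_frac`` of the call's bases
   are gap sequence;
3. support — fewer than ``min_support`` supporting reads (calls with no
   reported support, e.g. from read-depth callers, bypass this rule and
   are counted in the report);
4. size — shorter than ``min_size`` bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core import GapTrack, VariantCall

logger = logging.getLogger("cnvcons")

__all__ = ["FilterConfig", "FilterReport", "filter_calls"]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the pre-consensus filters.

    Defaults: 100-bp gap window at breakpoints, 25% maximum gap content,
    minimum 3 supporting reads, minimum call size 50 bp (the lower bound
    of the CNV size definition).
    """

    window: int = 100
    max_gap_frac: float = 0.25
    min_support: int = 3
    min_size: int = 50

    def __post_init__(self) -> None:
        if self.window < 0 or self.min_support < 0 or self.min_size < 0:
            raise ValueError("filter thresholds must be non-negative")
        if not 0.0 <= self.max_gap_frac <= 1.0:
            raise ValueError("max_gap_frac must be in [0, 1]")


@dataclass
class FilterReport:
    """Removal accounting; categories partition the removed calls."""

    n_input: int = 0
    n_removed_gap_breakpoint: int = 0
    n_removed_gap_fraction: int = 0
    n_removed_support: int = 0
    n_removed_min_size: int = 0
    n_retained: int = 0
    n_support_bypassed: int = 0  # calls with no support value (rule skipped)

    def balances(self) -> bool:
        return self.n_input == (
            self.n_retained + self.n_removed_gap_breakpoint
            + self.n_removed_gap_fraction + self.n_removed_support
            + self.n_removed_min_size
        )

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_removed_gap_breakpoint": self.n_removed_gap_breakpoint,
            "n_removed_gap_fraction": self.n_removed_gap_fraction,
            "n_removed_support": self.n_removed_support,
            "n_removed_min_size": self.n_removed_min_size,
            "n_retained": self.n_retained,
            "n_support_bypassed": self.n_support_bypassed,
        }


def filter_calls(
    calls: Sequence[VariantCall],
    gaps: GapTrack,
    config: FilterConfig = FilterConfig(),
) -> tuple[list, FilterReport]:
    """Apply the pre-consensus filters; returns (retained, report).

    Gap-content removal uses a strict inequality (drop iff fraction is
    strictly greater than ``max_gap_frac``).  Filtering is idempotent:
    re-filtering the retained set removes nothing.
    """
    report = FilterReport(n_input=len(calls))
    retained: list[VariantCall] = []
    for call in calls:
        iv = call.interval
        if gaps.gap_near_breakpoint(iv, config.window):
            report.n_removed_gap_breakpoint += 1
            continue
        if gaps.gap_fraction(iv) > config.max_gap_frac:
            report.n_removed_gap_fraction += 1
            continue
        if call.support_reads is None:
            report.n_support_bypassed += 1
        elif call.support_reads < config.min_support:
            report.n_removed_support += 1
            continue
        if iv.length < config.min_size:
            report.n_removed_min_size += 1
            continue
        retained.append(call)
    report.n_retained = len(retained)
    if report.n_support_bypassed:
        logger.info(
            "support filter bypassed for %d call(s) without a support value",
            report.n_support_bypassed,
        )
    return retained, report
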
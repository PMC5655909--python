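"""Domain types and interval algebra for CNV consensus calling.

Coordinates are 1-based inclusive throughout the in-memory model, matching
the genomic convention in which a variant of length L spans positions
``start .. start + L - 1`` and ``length = end - start + 1``.  Conversion to
0-based half-open happens only at BED boundaries (see :mod:`cnvcons.io`).

The three primitives every pipeline stage builds on are

* :func:`reciprocal_overlap` — the fraction of sequence two intervals
  mutually share, ``min(ovl/len_a, ovl/len_b)``;
* :func:`breakpoints_match` — agreement of both breakpoints within a
  base-pair tolerance, the matching rule used for split-read caller pairs;
* :class:`GapTrack` — assembly-gap ('N' run) arithmetic used to discard
  calls whose breakpoints sit in unassembled sequence.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "VariantCall",
    "ConsensusVariant",
    "CNVRegion",
    "GapTrack",
    "IntervalError",
    "reciprocal_overlap",
    "breakpoints_match",
    "overlap_bp",
    "DEFAULT_TOOLS",
    "SVTYPES",
    "REGION_TYPES",
]

#: default caller registry: read-depth, paired-end, and two split-read/PEM tools
DEFAULT_TOOLS = ("cnvnator", "breakdancer", "pindel", "delly")

SVTYPES = ("DEL", "DUP")
REGION_TYPES = ("deletion-only", "duplication-only", "CNVR")


class IntervalError(ValueError):
    """Raised for malformed genomic intervals (end < start, start < 1)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive genomic interval.

    Invariants: ``start >= 1``, ``end >= start``; length is
    ``end - start + 1`` and therefore always >= 1.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise IntervalError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise IntervalError(
                f"end < start: {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class VariantCall:
    """One raw CNV call emitted by one tool for one sample.

    ``support_reads`` may be ``None`` for callers that do not report a
    supporting-read count (read-depth callers report windows); such calls
    bypass the minimum-support filter with a logged count.
    ``run_id`` identifies the sequencing run, used to group calls of
    twice-sequenced animals.
    """

    interval: GenomicInterval
    svtype: str
    tool: str
    sample_id: str
    support_reads: Optional[int] = None
    run_id: str = "run1"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"svtype must be DEL or DUP, got {self.svtype!r}")
        if self.support_reads is not None and self.support_reads < 0:
            raise ValueError("support_reads must be >= 0")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class ConsensusVariant:
    """A within-sample variant supported by at least two different tools."""

    interval: GenomicInterval
    svtype: str
    sample_id: str
    tools: frozenset
    source_calls: list
    tool_pairs: frozenset  # set of frozenset({tool_a, tool_b}) that matched

    def __post_init__(self) -> None:
        if len(self.tools) < 2:
            raise ValueError("a consensus variant needs >= 2 distinct tools")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class CNVRegion:
    """A cross-sample merged region.

    ``region_type`` is ``deletion-only`` / ``duplication-only`` when all
    member variants share one type, and ``CNVR`` when both deletions and
    duplications contributed.  The interval spans from the lowest 5'
    to the highest 3' position of all members.
    """

    interval: GenomicInterval
    region_type: str
    members: list  # of ConsensusVariant
    carriers: frozenset  # distinct sample ids
    region_id: str = ""

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def size(self) -> int:
        return self.interval.length

    @property
    def tool_pairs(self) -> frozenset:
        """Union of matched tool pairs over member consensus variants."""
        pairs: set = set()
        for m in self.members:
            pairs |= set(m.tool_pairs)
        return frozenset(pairs)

    @property
    def tools(self) -> frozenset:
        t: set = set()
        for m in self.members:
            t |= set(m.tools)
        return frozenset(t)


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------

def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if chroms differ)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Reciprocal overlap fraction: ``min(ovl/len(a), ovl/len(b))``.

    Returns 0.0 for intervals on different chromosomes or with no shared
    base.  Symmetric; 1.0 iff the intervals are identical.
    """
    ovl = overlap_bp(a, b)
    if ovl == 0:
        return 0.0
    return min(ovl / a.length, ovl / b.length)


def breakpoints_match(a: GenomicInterval, b: GenomicInterval, tol: int = 100) -> bool:
    """True iff both 5' and 3' breakpoints agree within ``tol`` bp.

    This is the matching rule applied to the split-read caller pair
    (pindel + delly), whose base-level breakpoint resolution makes a
    reciprocal-overlap criterion unnecessarily loose.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if a.chrom != b.chrom:
        return False
    return abs(a.start - b.start) <= tol and abs(a.end - b.end) <= tol


class GapTrack:
    """Per-chromosome sorted, coalesced assembly-gap intervals.

    Overlapping or book-ended input gaps are merged on construction, so the
    stored arrays are strictly sorted and disjoint, allowing binary-search
    queries for overlap totals and breakpoint proximity.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, spans in by_chrom.items():
            spans.sort()
            merged: list[list[int]] = []
            for s, e in spans:
                if merged and s <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._starts[chrom] = np.array([m[0] for m in merged], dtype=np.int64)
            self._ends[chrom] = np.array([m[1] for m in merged], dtype=np.int64)

    @property
    def chroms(self) -> tuple:
        return tuple(sorted(self._starts))

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            for s, e in zip(self._starts[chrom], self._ends[chrom]):
                yield GenomicInterval(chrom, int(s), int(e))

    def overlap_bp(self, v: GenomicInterval) -> int:
        """Total gap bases inside ``v``."""
        starts = self._starts.get(v.chrom)
        if starts is None or len(starts) == 0:
            return 0
        ends = self._ends[v.chrom]
        lo = int(np.searchsorted(ends, v.start, side="left"))
        hi = int(np.searchsorted(starts, v.end, side="right"))
        if hi <= lo:
            return 0
        s = np.maximum(starts[lo:hi], v.start)
        e = np.minimum(ends[lo:hi], v.end)
        return int(np.sum(e - s + 1))

    def gap_fraction(self, v: GenomicInterval) -> float:
        """Fraction of ``v``'s bases that are gap ('N') sequence."""
        return self.overlap_bp(v) / v.length

    def any_gap_in(self, chrom: str, lo: int, hi: int) -> bool:
        """True iff any gap base lies in [lo, hi] on ``chrom``."""
        if hi < lo:
            return False
        lo = max(lo, 1)
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return False
        ends = self._ends[chrom]
        i = int(np.searchsorted(ends, lo, side="left"))
        return i < len(starts) and int(starts[i]) <= hi

    def gap_near_breakpoint(self, v: GenomicInterval, window: int = 100) -> bool:
        """True iff a gap base lies within ``window`` bp of either breakpoint.

        The window is symmetric around each breakpoint: ``[p - window,
        p + window]`` for ``p`` in ``{v.start, v.end}``.
        """
        if window < 0:
            raise ValueError("window must be >= 0")
        return self.any_gap_in(v.chrom, v.start - window, v.start + window) or \
            self.any_gap_in(v.chrom, v.end - window, v.end + window)
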
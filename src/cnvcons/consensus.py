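"""Within-sample multi-tool consensus.

A variant is retained only if at least two different callers predicted it
in the same sample.  "The same variant" is decided by a tool-pair-specific
matching rule:

* for the designated breakpoint-resolution pair (default pindel + delly),
  both breakpoints must agree within ``bp_tol`` bp (default 100);
* for every other pair of tools, the two calls must share at least
  ``ro_thresh`` (default 90%) reciprocal overlap.

Matching calls of the same type within a sample form a graph; each
connected component with >= 2 distinct tools becomes one
:class:`~cnvcons.core.ConsensusVariant` spanning the union of its member
calls.  Deletions and duplications never merge at this stage — the two
types only meet later, at the region level.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import pandas as pd

from .core import (
    ConsensusVariant,
    GenomicInterval,
    VariantCall,
    breakpoints_match,
    reciprocal_overlap,
)

__all__ = ["ConsensusConfig", "match_rule", "build_consensus", "combination_counts"]


@dataclass(frozen=True)
class ConsensusConfig:
    """Matching thresholds for the two-tool consensus step.

    ``bp_pair`` names the tool pair matched by breakpoint proximity
    instead of reciprocal overlap.  With ``strict_bp_pair`` the
    breakpoint rule is required *in addition to* the reciprocal-overlap
    rule for that pair rather than replacing it.  ``clique_mode``
    requires every cross-tool pair of calls in a component to match
    (default is single-linkage connected components).
    """

    bp_pair: frozenset = frozenset({"pindel", "delly"})
    bp_tol: int = 100
    ro_thresh: float = 0.90
    strict_bp_pair: bool = False
    clique_mode: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.ro_thresh <= 1.0:
            raise ValueError("ro_thresh must be in [0, 1]")
        if self.bp_tol < 0:
            raise ValueError("bp_tol must be >= 0")


def match_rule(
    tool_a: str,
    tool_b: str,
    a: VariantCall,
    b: VariantCall,
    config: ConsensusConfig = ConsensusConfig(),
) -> bool:
    """Decide whether two different-tool calls are the same variant."""
    if tool_a == tool_b:
        raise ValueError("match_rule requires two different tools")
    if frozenset({tool_a, tool_b}) == config.bp_pair:
        bp_ok = breakpoints_match(a.interval, b.interval, config.bp_tol)
        if config.strict_bp_pair:
            return bp_ok and reciprocal_overlap(a.interval, b.interval) >= config.ro_thresh
        return bp_ok
    return reciprocal_overlap(a.interval, b.interval) >= config.ro_thresh


def _edges(group: list, config: ConsensusConfig):
    """Yield index pairs of matching calls within one (svtype, chrom) group.

    Calls are start-sorted; a later call can only match an earlier one if
    it starts before ``max(end, start + bp_tol)`` of the earlier call, so
    the scan breaks early on sorted input.
    """
    order = sorted(range(len(group)), key=lambda i: (group[i].start, group[i].end))
    for pos, i in enumerate(order):
        a = group[i]
        horizon = max(a.end, a.start + config.bp_tol)
        for j in order[pos + 1:]:
            b = group[j]
            if b.start > horizon:
                break
            if a.tool != b.tool and match_rule(a.tool, b.tool, a, b, config):
                yield i, j


def build_consensus(
    calls: Sequence[VariantCall],
    config: ConsensusConfig = ConsensusConfig(),
) -> list:
    """Build consensus variants for one sample's filtered calls.

    Returns one :class:`ConsensusVariant` per connected component of the
    match graph containing >= 2 distinct tools, with the component span
    (min start .. max end), the distinct tool set, and the set of tool
    pairs for which at least one matching edge existed.  Single-tool
    components and singletons are discarded.  Output order is
    deterministic: (chrom, start, end, svtype).
    """
    samples = {c.sample_id for c in calls}
    if len(samples) > 1:
        raise ValueError(f"build_consensus expects calls from one sample, got {sorted(samples)}")

    groups: dict[tuple, list] = defaultdict(list)
    for c in calls:
        groups[(c.svtype, c.chrom)].append(c)

    out: list[ConsensusVariant] = []
    for (svtype, chrom), group in groups.items():
        g = nx.Graph()
        g.add_nodes_from(range(len(group)))
        g.add_edges_from(_edges(group, config))
        for comp in nx.connected_components(g):
            members = [group[i] for i in comp]
            tools = frozenset(m.tool for m in members)
            if len(tools) < 2:
                continue
            if config.clique_mode and not _is_clique(members, config):
                continue
            pairs = frozenset(
                frozenset({group[i].tool, group[j].tool})
                for i, j in g.edges(comp)
                if group[i].tool != group[j].tool
            )
            out.append(ConsensusVariant(
                interval=GenomicInterval(
                    chrom,
                    min(m.start for m in members),
                    max(m.end for m in members),
                ),
                svtype=svtype,
                sample_id=members[0].sample_id,
                tools=tools,
                source_calls=sorted(members, key=lambda m: (m.start, m.end, m.tool)),
                tool_pairs=pairs,
            ))
    out.sort(key=lambda v: (v.chrom, v.start, v.end, v.svtype))
    return out


def _is_clique(members: list, config: ConsensusConfig) -> bool:
    for a, b in itertools.combinations(members, 2):
        if a.tool != b.tool and not match_rule(a.tool, b.tool, a, b, config):
            return False
    return True


def combination_counts(items: Iterable, tools: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Count distinct variants (or regions) per unordered tool pair.

    ``items`` may be consensus variants or regions — anything exposing a
    ``tool_pairs`` attribute.  A variant supported by k tools contributes
    to up to C(k, 2) rows, so the rows sum to >= the number of items.
    When ``tools`` is given, all C(n, 2) pairs appear (zero-filled).
    """
    counts: dict[frozenset, int] = defaultdict(int)
    total = 0
    for it in items:
        total += 1
        for pair in it.tool_pairs:
            counts[frozenset(pair)] += 1
    if tools is not None:
        for pair in itertools.combinations(sorted(tools), 2):
            counts.setdefault(frozenset(pair), 0)
    rows = []
    for pair, n in counts.items():
        a, b = sorted(pair)
        rows.append({"tool_a": a, "tool_b": b, "n_variants": n})
    df = pd.DataFrame(rows, columns=["tool_a", "tool_b", "n_variants"])
    df = df.sort_values(["tool_a", "tool_b"], ignore_index=True)
    df.attrs["n_items"] = total
    return df
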
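"""Region validation: Mendelian, replicate-run, and external-array support.

A region in the final retained set is *validated* when it passes the
Mendelian check OR the twice-sequenced (replicate-run) check OR is
matched by an array-CGH call; SNP-array support is recorded as an
additional confirmation column but does not itself retain a region.

Rounding conventions for reports: validation rates to one decimal,
prose percentages to the nearest integer — both half-up, matching how
such tables are conventionally printed.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core import CNVRegion, GenomicInterval, VariantCall, reciprocal_overlap
from .io import PedigreeRecord

__all__ = [
    "ValidationFlags",
    "mendelian_validate",
    "replicate_validate",
    "external_validate",
    "validation_summary",
    "validation_rate",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (1 decimal for rates, 0 for percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def validation_rate(validated: int, predicted: int) -> float:
    """Percentage of predicted variants that validated, 1 decimal half-up.

    Returns NaN when nothing was predicted (rate is undefined).
    """
    if predicted == 0:
        return float("nan")
    return round_half_up(100.0 * validated / predicted, 1)


@dataclass
class ValidationFlags:
    """Per-region validation outcome across the four strategies."""

    region_id: str
    mendelian: bool = False
    twice_sequenced: bool = False
    cgh: bool = False
    snp_array: bool = False

    @property
    def validated(self) -> bool:
        return self.mendelian or self.twice_sequenced or self.cgh


def _init_flags(regions: Sequence[CNVRegion]) -> dict:
    return {r.region_id: ValidationFlags(r.region_id) for r in regions}


def _ensure_flags(regions, flags):
    if flags is None:
        flags = _init_flags(regions)
    else:
        for r in regions:
            flags.setdefault(r.region_id, ValidationFlags(r.region_id))
    return flags


# ---------------------------------------------------------------------------
# Mendelian
# ---------------------------------------------------------------------------

def mendelian_validate(
    regions: Sequence[CNVRegion],
    pedigree: Sequence[PedigreeRecord],
    cohort_ids: Optional[Iterable[str]] = None,
    flags: Optional[dict] = None,
) -> tuple[dict, pd.DataFrame]:
    """Mark regions carried by an offspring and at least one of its parents.

    A region is Mendelian-validated as soon as one pedigree record shows
    transmission (offspring is a carrier and a listed parent is too).
    The second return value is a transmission table with, for each
    (parent, offspring) link, the number of regions the parent carries
    and the fraction of them the offspring also carries.
    """
    if cohort_ids is not None:
        known = set(cohort_ids)
        for rec in pedigree:
            for sid in (rec.offspring_id, *rec.parents):
                if sid not in known:
                    raise ValueError(f"pedigree references unknown sample {sid!r}")

    flags = _ensure_flags(regions, flags)
    rows = []
    link_shared: dict[tuple, list[int]] = {}
    for rec in pedigree:
        for parent in rec.parents:
            link_shared[(parent, rec.offspring_id)] = [0, 0]  # carried, shared
    for r in regions:
        for rec in pedigree:
            if rec.offspring_id not in r.carriers:
                continue
            if any(p in r.carriers for p in rec.parents):
                flags[r.region_id].mendelian = True
        for (parent, offspring), acc in link_shared.items():
            if parent in r.carriers:
                acc[0] += 1
                if offspring in r.carriers:
                    acc[1] += 1
    for (parent, offspring), (carried, shared) in sorted(link_shared.items()):
        rows.append({
            "parent": parent,
            "offspring": offspring,
            "n_parent_carried": carried,
            "n_shared": shared,
            "fraction_transmitted": shared / carried if carried else float("nan"),
        })
    table = pd.DataFrame(
        rows, columns=["parent", "offspring", "n_parent_carried", "n_shared",
                       "fraction_transmitted"])
    return flags, table


def pedigree_seen_count(regions: Sequence[CNVRegion],
                        pedigree: Sequence[PedigreeRecord]) -> int:
    """Number of regions carried by any pedigree member.

    This is the denominator of the Mendelian-validated percentage: the
    fraction is computed over variants observable in trios/pairs at all.
    """
    members = set()
    for rec in pedigree:
        members.add(rec.offspring_id)
        members.update(rec.parents)
    return sum(1 for r in regions if r.carriers & members)


# ---------------------------------------------------------------------------
# twice-sequenced replicates
# ---------------------------------------------------------------------------

def _type_matches(region_type: str, svtype: str) -> bool:
    if region_type == "deletion-only":
        return svtype == "DEL"
    if region_type == "duplication-only":
        return svtype == "DUP"
    return True  # CNVR: either type counts


def replicate_validate(
    regions: Sequence[CNVRegion],
    run_calls: Mapping[tuple, Sequence],
    match_thresh: float = 0.70,
    flags: Optional[dict] = None,
) -> tuple[dict, float]:
    """Validate regions recurring in every sequencing run of a replicate animal.

    ``run_calls`` maps ``(sample_id, run_id)`` to that run's call list —
    by default the per-run *filtered raw calls*, so recurrence only needs
    any one detection tool per run; pass per-run consensus variants
    instead for region-level matching.  A region validates if some
    twice-sequenced animal carries it and a call of the matching type
    with reciprocal overlap >= ``match_thresh`` to the region span
    appears in every one of that animal's runs.  The second return value
    is the concordance rate over regions carried by replicate animals.
    """
    runs_by_sample: dict[str, list] = defaultdict(list)
    for (sample_id, run_id) in run_calls:
        runs_by_sample[sample_id].append(run_id)
    for sample_id, runs in runs_by_sample.items():
        if len(runs) < 2:
            raise ValueError(
                f"replicate animal {sample_id!r} has a single run {runs}; "
                "twice-sequenced validation needs >= 2 runs"
            )

    flags = _ensure_flags(regions, flags)
    n_carried = 0
    n_validated = 0
    for r in regions:
        rep_carriers = [s for s in r.carriers if s in runs_by_sample]
        if not rep_carriers:
            continue
        n_carried += 1
        ok = False
        for sample_id in rep_carriers:
            if all(
                any(
                    _type_matches(r.region_type, c.svtype)
                    and reciprocal_overlap(c.interval, r.interval) >= match_thresh
                    for c in run_calls[(sample_id, run_id)]
                )
                for run_id in runs_by_sample[sample_id]
            ):
                ok = True
                break
        if ok:
            flags[r.region_id].twice_sequenced = True
            n_validated += 1
    rate = n_validated / n_carried if n_carried else float("nan")
    return flags, rate


# ---------------------------------------------------------------------------
# external arrays (CGH / SNP genotyping)
# ---------------------------------------------------------------------------

def external_validate(
    regions: Sequence[CNVRegion],
    external_calls: Sequence[VariantCall],
    ro_thresh: float = 0.50,
    per_sample: bool = True,
    flag_attr: str = "cgh",
    flags: Optional[dict] = None,
) -> dict:
    """Match regions against an external (array-derived) call set.

    A region validates when some external call overlaps it at
    reciprocal overlap >= ``ro_thresh``; with ``per_sample`` the match
    must come from an animal that carries the region and be of the
    matching variant-type class.  Relaxed re-checks (e.g. 0.20 or 0.01)
    are just lower thresholds.  ``flag_attr`` selects which flag column
    is set ('cgh' or 'snp_array').
    """
    if flag_attr not in ("cgh", "snp_array"):
        raise ValueError("flag_attr must be 'cgh' or 'snp_array'")
    flags = _ensure_flags(regions, flags)
    by_chrom: dict[str, list] = defaultdict(list)
    for c in external_calls:
        by_chrom[c.chrom].append(c)
    for r in regions:
        for c in by_chrom.get(r.chrom, ()):
            if per_sample and c.sample_id not in r.carriers:
                continue
            if per_sample and not _type_matches(r.region_type, c.svtype):
                continue
            if reciprocal_overlap(c.interval, r.interval) >= ro_thresh:
                setattr(flags[r.region_id], flag_attr, True)
                break
    return flags


# ---------------------------------------------------------------------------
# summary report
# ---------------------------------------------------------------------------

def validation_summary(
    items: Sequence,
    flags: Mapping[str, ValidationFlags],
    tools: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-tool-pair predicted/validated counts and validation rates.

    ``items`` are regions (or consensus variants carrying a
    ``region_id``-like id) exposing ``tool_pairs``.  The rate column is
    ``100 * validated / predicted`` to one decimal (half-up); pairs with
    nothing predicted get NaN.  A 'Total' row counts distinct items, not
    the column sums (an item supported by k tools appears in C(k, 2)
    pair rows).
    """
    pair_pred: dict[frozenset, int] = defaultdict(int)
    pair_val: dict[frozenset, int] = defaultdict(int)
    total_pred = 0
    total_val = 0
    for it in items:
        fid = getattr(it, "region_id", None)
        fl = flags.get(fid)
        ok = bool(fl and fl.validated)
        total_pred += 1
        total_val += ok
        for pair in it.tool_pairs:
            pair_pred[frozenset(pair)] += 1
            if ok:
                pair_val[frozenset(pair)] += 1
    if tools is not None:
        import itertools
        for pair in itertools.combinations(sorted(tools), 2):
            pair_pred.setdefault(frozenset(pair), 0)
    rows = []
    for pair in sorted(pair_pred, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        pred = pair_pred[pair]
        val = pair_val.get(pair, 0)
        rows.append({
            "combination": f"{a} + {b}",
            "n_predicted": pred,
            "n_validated": val,
            "validation_rate_pct": validation_rate(val, pred),
        })
    rows.append({
        "combination": "Total",
        "n_predicted": total_pred,
        "n_validated": total_val,
        "validation_rate_pct": validation_rate(total_val, total_pred),
    })
    return pd.DataFrame(
        rows, columns=["combination", "n_predicted", "n_validated",
                       "validation_rate_pct"])


def mendelian_percentage(n_validated: int, n_seen_in_pedigree: int) -> float:
    """Prose-style Mendelian percentage, nearest integer half-up."""
    if n_seen_in_pedigree == 0:
        return float("nan")
    return round_half_up(100.0 * n_validated / n_seen_in_pedigree, 0)
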
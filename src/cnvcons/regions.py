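"""Cross-sample merging of consensus variants into CNV regions.

Consensus variants from different samples (any type) are clustered by
single-linkage at >= 70% reciprocal overlap on the same chromosome.  Each
cluster becomes one region whose 5' and 3' bounds are the lowest start and
highest end over all member variants; a region is typed ``deletion-only``
or ``duplication-only`` when all members share one type and ``CNVR`` when
both deletions and duplications contributed.  Singleton variants are kept
as singleton regions (unique, single-sample variants are reported, not
dropped).

Single-linkage transitivity means chains of pairwise-overlapping variants
can produce regions much larger than any member — multi-megabase regions
arise this way on real cohorts.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .core import CNVRegion, ConsensusVariant, GenomicInterval, reciprocal_overlap
from .io import SampleMeta

__all__ = [
    "cluster_across_samples",
    "build_region",
    "build_regions",
    "RegionSummary",
    "summarize_regions",
]


def cluster_across_samples(
    variants: Sequence[ConsensusVariant],
    ro_thresh: float = 0.70,
) -> list:
    """Single-linkage clusters of variants at >= ``ro_thresh`` reciprocal overlap.

    Variants of either type and from any sample may join a cluster; an
    edge additionally requires at least one shared base (so at a
    threshold of 0 only touching intervals merge).  Clusters are ordered
    by (chrom, min start, min end) and variants within a cluster by
    (start, end, sample_id).
    """
    if not 0.0 <= ro_thresh <= 1.0:
        raise ValueError("ro_thresh must be in [0, 1]")
    by_chrom: dict[str, list] = defaultdict(list)
    for v in variants:
        by_chrom[v.chrom].append(v)

    clusters: list[list] = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda v: (v.start, v.end, v.sample_id))
        g = nx.Graph()
        g.add_nodes_from(range(len(group)))
        for i, a in enumerate(group):
            for j in range(i + 1, len(group)):
                b = group[j]
                if b.start > a.end:
                    break  # no shared base possible beyond this start
                if reciprocal_overlap(a.interval, b.interval) >= ro_thresh:
                    g.add_edge(i, j)
        for comp in nx.connected_components(g):
            members = sorted(
                (group[i] for i in comp),
                key=lambda v: (v.start, v.end, v.sample_id),
            )
            clusters.append(members)
    clusters.sort(key=lambda ms: (ms[0].chrom, min(m.start for m in ms),
                                  min(m.end for m in ms)))
    return clusters


def build_region(cluster: Sequence[ConsensusVariant], region_id: str = "") -> CNVRegion:
    """Build one region from a cluster: span = (min start, max end)."""
    if not cluster:
        raise ValueError("cannot build a region from an empty cluster")
    chroms = {v.chrom for v in cluster}
    if len(chroms) > 1:
        raise ValueError(f"cluster spans multiple chromosomes: {sorted(chroms)}")
    svtypes = {v.svtype for v in cluster}
    if svtypes == {"DEL"}:
        region_type = "deletion-only"
    elif svtypes == {"DUP"}:
        region_type = "duplication-only"
    else:
        region_type = "CNVR"
    return CNVRegion(
        interval=GenomicInterval(
            cluster[0].chrom,
            min(v.start for v in cluster),
            max(v.end for v in cluster),
        ),
        region_type=region_type,
        members=list(cluster),
        carriers=frozenset(v.sample_id for v in cluster),
        region_id=region_id,
    )


def build_regions(
    variants: Sequence[ConsensusVariant],
    ro_thresh: float = 0.70,
    id_prefix: str = "CNVR",
) -> list:
    """Cluster and build all regions with sequential zero-padded ids.

    Ids are assigned in (chrom, start) order; the numbering is an
    artifact of this run, not a stable identifier across datasets.
    """
    clusters = cluster_across_samples(variants, ro_thresh)
    width = max(5, len(str(len(clusters))))
    regions = [
        build_region(c, f"{id_prefix}_{i + 1:0{width}d}")
        for i, c in enumerate(clusters)
    ]
    return regions


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------

@dataclass
class RegionSummary:
    """Cohort-level region statistics.

    * ``per_chrom`` — region counts by type, union bp covered and the
      covered fraction per chromosome;
    * ``per_sample`` — carried-region counts and genome fraction per
      animal;
    * ``size_quantiles`` — 25/50/75% size quantiles per region type;
    * ``corr_chrom_count`` — Pearson r (and p) of per-chromosome region
      count vs chromosome length;
    * ``corr_coverage_count`` — Pearson r (and p) of per-sample count vs
      sequencing coverage;
    * ``breed_chi2`` — chi-square test of per-breed region counts against
      expectation proportional to animals sequenced per breed.
    """

    per_chrom: pd.DataFrame
    per_sample: pd.DataFrame
    size_quantiles: pd.DataFrame
    corr_chrom_count: tuple
    corr_coverage_count: tuple
    breed_chi2: dict
    genome_length: int = 0
    total_covered_bp: int = 0


def _union_bp(intervals: list) -> int:
    """Union length of (start, end) 1-based inclusive spans."""
    if not intervals:
        return 0
    intervals = sorted(intervals)
    total = 0
    cur_s, cur_e = intervals[0]
    for s, e in intervals[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    total += cur_e - cur_s + 1
    return total


def summarize_regions(
    regions: Sequence[CNVRegion],
    sample_meta: Sequence[SampleMeta],
    chrom_lengths: dict,
) -> RegionSummary:
    """Compute cohort summary statistics over the final region set."""
    unknown = sorted({r.chrom for r in regions} - set(chrom_lengths))
    if unknown:
        raise ValueError(f"regions on chromosomes without a length: {unknown}")

    # per-chromosome table
    rows = []
    total_covered = 0
    by_chrom: dict[str, list] = defaultdict(list)
    for r in regions:
        by_chrom[r.chrom].append(r)
    for chrom, length in chrom_lengths.items():
        rs = by_chrom.get(chrom, [])
        covered = _union_bp([(r.start, r.end) for r in rs])
        total_covered += covered
        rows.append({
            "chrom": chrom,
            "length": length,
            "n_regions": len(rs),
            "n_deletion_only": sum(r.region_type == "deletion-only" for r in rs),
            "n_duplication_only": sum(r.region_type == "duplication-only" for r in rs),
            "n_cnvr": sum(r.region_type == "CNVR" for r in rs),
            "covered_bp": covered,
            "covered_frac": covered / length,
        })
    per_chrom = pd.DataFrame(rows)

    # per-sample table
    genome_length = int(sum(chrom_lengths.values()))
    meta_by_id = {m.sample_id: m for m in sample_meta}
    sample_regions: dict[str, list] = defaultdict(list)
    for r in regions:
        for s in r.carriers:
            sample_regions[s].append(r)
    srows = []
    for m in sample_meta:
        rs = sample_regions.get(m.sample_id, [])
        spans: dict[str, list] = defaultdict(list)
        for r in rs:
            spans[r.chrom].append((r.start, r.end))
        bp = sum(_union_bp(v) for v in spans.values())
        srows.append({
            "sample_id": m.sample_id,
            "breed": m.breed,
            "breed_type": m.breed_type,
            "coverage": m.coverage,
            "n_regions": len(rs),
            "covered_bp": bp,
            "genome_frac": bp / genome_length if genome_length else 0.0,
        })
    per_sample = pd.DataFrame(srows)

    # size quantiles per region type
    qrows = []
    for rtype in ("deletion-only", "duplication-only", "CNVR"):
        sizes = np.array([r.size for r in regions if r.region_type == rtype])
        if sizes.size:
            q25, q50, q75 = np.percentile(sizes, [25, 50, 75])
        else:
            q25 = q50 = q75 = float("nan")
        qrows.append({"region_type": rtype, "n": int(sizes.size),
                      "q25": q25, "median": q50, "q75": q75})
    size_quantiles = pd.DataFrame(qrows)

    # correlations (constant input would make Pearson undefined)
    def _pearson(x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        if len(x) < 2 or np.std(x) == 0 or np.std(y) == 0:
            return (float("nan"), float("nan"))
        r = stats.pearsonr(x, y)
        return (float(r.statistic), float(r.pvalue))

    corr_chrom = _pearson(per_chrom["length"], per_chrom["n_regions"])
    corr_cov = _pearson(per_sample["coverage"], per_sample["n_regions"]) \
        if len(per_sample) else (float("nan"), float("nan"))

    # chi-square: observed per-breed counts vs expectation proportional to
    # the number of sequenced animals in each breed
    breed_n = defaultdict(int)
    for m in sample_meta:
        breed_n[m.breed] += 1
    breed_counts = defaultdict(int)
    for r in regions:
        breeds = {meta_by_id[s].breed for s in r.carriers if s in meta_by_id}
        for b in breeds:
            breed_counts[b] += 1
    breeds = sorted(breed_n)
    observed = np.array([breed_counts.get(b, 0) for b in breeds], dtype=float)
    n_animals = np.array([breed_n[b] for b in breeds], dtype=float)
    if observed.sum() > 0:
        expected = observed.sum() * n_animals / n_animals.sum()
        chi2, p = stats.chisquare(observed, expected)
        breed_chi2 = {
            "breeds": breeds,
            "observed": observed.tolist(),
            "expected": expected.tolist(),
            "statistic": float(chi2),
            "pvalue": float(p),
        }
    else:
        breed_chi2 = {"breeds": breeds, "observed": observed.tolist(),
                      "expected": [], "statistic": float("nan"),
                      "pvalue": float("nan")}

    return RegionSummary(
        per_chrom=per_chrom,
        per_sample=per_sample,
        size_quantiles=size_quantiles,
        corr_chrom_count=corr_chrom,
        corr_coverage_count=corr_cov,
        breed_chi2=breed_chi2,
        genome_length=genome_length,
        total_covered_bp=total_covered,
    )
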
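"""Gene/QTL annotation and carrier-frequency reporting.

Regions are intersected with gene and QTL intervals; each overlap is
classified as *partial*, *feature_contained* (the region spans the entire
gene — an entire-gene deletion or duplication), or *region_contained*
(the region lies wholly inside the feature).  Cohort tallies are exposed
at both the region level (regions hitting >= 1 gene) and the feature
level (distinct genes hit) because the two units answer different
questions.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CNVRegion, GenomicInterval, overlap_bp
from .io import AnnotationRecord, SampleMeta

__all__ = [
    "classify_overlap",
    "annotate_regions",
    "AnnotationResult",
    "frequency_report",
    "FrequencyReport",
]


def classify_overlap(region: GenomicInterval, feature: GenomicInterval) -> str:
    """Classify how a region overlaps a feature.

    Returns one of ``none`` (no shared base), ``feature_contained``
    (feature inside the region), ``region_contained`` (region inside the
    feature), or ``partial``.  When region and feature are identical both
    containments hold; ``feature_contained`` is reported.
    """
    if overlap_bp(region, feature) == 0:
        return "none"
    if region.start <= feature.start and feature.end <= region.end:
        return "feature_contained"
    if feature.start <= region.start and region.end <= feature.end:
        return "region_contained"
    return "partial"


@dataclass
class AnnotationResult:
    """Per-region overlap table plus cohort tallies."""

    table: pd.DataFrame  # region_id, feature_id, feature_class, label, overlap_class
    tallies: dict


def annotate_regions(
    regions: Sequence[CNVRegion],
    features: Sequence[AnnotationRecord],
) -> AnnotationResult:
    """Intersect regions with annotation features and tally the cohort.

    Tallies include: regions with >= 1 gene, distinct genes hit,
    entire-gene deletions/duplications (regions of the matching type
    fully containing a gene), CNVR fully containing a gene, regions with
    QTL overlap, and regions overlapping both genes and QTL.
    """
    by_chrom: dict[str, list] = defaultdict(list)
    for f in features:
        by_chrom[f.interval.chrom].append(f)
    for lst in by_chrom.values():
        lst.sort(key=lambda f: (f.interval.start, f.interval.end))

    rows = []
    regions_with_gene: set = set()
    regions_with_qtl: set = set()
    genes_hit: set = set()
    entire_gene_del: set = set()
    entire_gene_dup: set = set()
    entire_gene_cnvr: set = set()
    for r in regions:
        for f in by_chrom.get(r.chrom, ()):
            if f.interval.start > r.end:
                break
            cls = classify_overlap(r.interval, f.interval)
            if cls == "none":
                continue
            rows.append({
                "region_id": r.region_id,
                "region_type": r.region_type,
                "feature_id": f.feature_id,
                "feature_class": f.feature_class,
                "label": f.label,
                "overlap_class": cls,
            })
            if f.feature_class == "gene":
                regions_with_gene.add(r.region_id)
                genes_hit.add(f.feature_id)
                if cls == "feature_contained":
                    if r.region_type == "deletion-only":
                        entire_gene_del.add(r.region_id)
                    elif r.region_type == "duplication-only":
                        entire_gene_dup.add(r.region_id)
                    else:
                        entire_gene_cnvr.add(r.region_id)
            else:
                regions_with_qtl.add(r.region_id)
    table = pd.DataFrame(
        rows, columns=["region_id", "region_type", "feature_id",
                       "feature_class", "label", "overlap_class"])
    tallies = {
        "n_regions_with_gene": len(regions_with_gene),
        "n_distinct_genes": len(genes_hit),
        "n_entire_gene_deletion_regions": len(entire_gene_del),
        "n_entire_gene_duplication_regions": len(entire_gene_dup),
        "n_entire_gene_cnvr": len(entire_gene_cnvr),
        "n_regions_with_qtl": len(regions_with_qtl),
        "n_regions_with_gene_and_qtl": len(regions_with_gene & regions_with_qtl),
    }
    return AnnotationResult(table=table, tallies=tallies)


@dataclass
class FrequencyReport:
    """Carrier-frequency and breed-sharing tables."""

    table: pd.DataFrame
    carrier_freq_hist: pd.DataFrame  # carrier_pct bin edges + counts
    breeds_per_region_hist: pd.DataFrame


def frequency_report(
    regions: Sequence[CNVRegion],
    sample_meta: Sequence[SampleMeta],
    all_breeds: Optional[Sequence[str]] = None,
) -> FrequencyReport:
    """Per-region carrier frequency, breed sharing and breed-type class.

    Carrier percentage denominators use distinct animals (twice-sequenced
    animals count once).  ``breed_type_class`` is dairy-only / beef-only /
    both; ``shared_by_all_breeds`` compares against the configured breed
    list (default: breeds present in the metadata).
    """
    meta_by_id = {m.sample_id: m for m in sample_meta}
    n_animals = len(meta_by_id)
    if all_breeds is None:
        all_breeds = sorted({m.breed for m in sample_meta})
    all_breeds = list(all_breeds)

    rows = []
    for r in regions:
        missing = [s for s in r.carriers if s not in meta_by_id]
        if missing:
            raise ValueError(f"carriers missing from metadata: {sorted(missing)}")
        breeds = sorted({meta_by_id[s].breed for s in r.carriers})
        types = {meta_by_id[s].breed_type for s in r.carriers}
        if types == {"dairy"}:
            btclass = "dairy-only"
        elif types == {"beef"}:
            btclass = "beef-only"
        else:
            btclass = "both"
        rows.append({
            "region_id": r.region_id,
            "region_type": r.region_type,
            "n_carriers": len(r.carriers),
            "carrier_pct": 100.0 * len(r.carriers) / n_animals,
            "breeds": ",".join(breeds),
            "n_breeds": len(breeds),
            "breed_type_class": btclass,
            "breed_specific": len(breeds) == 1,
            "shared_by_all_breeds": set(breeds) >= set(all_breeds),
        })
    table = pd.DataFrame(
        rows, columns=["region_id", "region_type", "n_carriers", "carrier_pct",
                       "breeds", "n_breeds", "breed_type_class",
                       "breed_specific", "shared_by_all_breeds"])

    edges = np.arange(0, 101, 5)
    if len(table):
        counts, _ = np.histogram(table["carrier_pct"], bins=edges)
    else:
        counts = np.zeros(len(edges) - 1, dtype=int)
    freq_hist = pd.DataFrame({
        "bin_lo_pct": edges[:-1], "bin_hi_pct": edges[1:], "n_regions": counts,
    })
    nb = Counter(table["n_breeds"]) if len(table) else Counter()
    breeds_hist = pd.DataFrame({
        "n_breeds": list(range(1, len(all_breeds) + 1)),
        "n_regions": [nb.get(k, 0) for k in range(1, len(all_breeds) + 1)],
    })
    return FrequencyReport(table=table, carrier_freq_hist=freq_hist,
                           breeds_per_region_hist=breeds_hist)
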
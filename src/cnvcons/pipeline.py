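"""End-to-end orchestration: filter -> consensus -> regions -> validate -> annotate.

This is the library entry point behind the ``cnvcons run-all`` command.
Raw per-tool calls are filtered per (sample, run); within-sample
consensus is built on each sample's primary run; consensus variants are
merged across samples into regions; regions are validated by the
Mendelian, replicate-run and external-array strategies; and validated
regions are annotated and summarised.

Replicate (non-primary) runs participate only in the twice-sequenced
validation — carrier counts and region construction use one call set
per animal, so twice-sequenced animals contribute once.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .annotation import AnnotationResult, FrequencyReport, annotate_regions, frequency_report
from .consensus import ConsensusConfig, build_consensus, combination_counts
from .core import GapTrack, VariantCall
from .filtering import FilterConfig, FilterReport, filter_calls
from .io import AnnotationRecord, PedigreeRecord, SampleMeta
from .regions import RegionSummary, build_regions, summarize_regions
from .validation import (
    ValidationFlags,
    external_validate,
    mendelian_percentage,
    mendelian_validate,
    pedigree_seen_count,
    replicate_validate,
    validation_summary,
)

logger = logging.getLogger("cnvcons")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds of the workflow; defaults are the standard values
    (3 reads, 25% gap content, 100-bp windows, 90% within-sample RO,
    70% cross-sample RO, 50% external RO)."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    region_ro: float = 0.70
    replicate_ro: float = 0.70
    cgh_ro: float = 0.50
    snp_ro: float = 0.50

    def __post_init__(self) -> None:
        for name in ("region_ro", "replicate_ro", "cgh_ro", "snp_ro"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def as_dict(self) -> dict:
        return {
            "min_support": self.filter.min_support,
            "max_gap_frac": self.filter.max_gap_frac,
            "gap_window": self.filter.window,
            "min_size": self.filter.min_size,
            "consensus_ro": self.consensus.ro_thresh,
            "bp_tol": self.consensus.bp_tol,
            "bp_pair": "+".join(sorted(self.consensus.bp_pair)),
            "region_ro": self.region_ro,
            "replicate_ro": self.replicate_ro,
            "cgh_ro": self.cgh_ro,
            "snp_ro": self.snp_ro,
        }


@dataclass
class PipelineResult:
    filter_report: FilterReport
    filtered_calls: dict  # (sample_id, run_id) -> list[VariantCall]
    consensus: list  # ConsensusVariant, primary runs only
    regions: list  # all CNVRegion
    flags: dict  # region_id -> ValidationFlags
    validated_regions: list
    summary: Optional[RegionSummary] = None
    validation_table: Optional[object] = None  # pandas DataFrame
    combination_table: Optional[object] = None
    replicate_concordance: float = float("nan")
    mendelian_pct: float = float("nan")
    transmission_table: Optional[object] = None
    annotation: Optional[AnnotationResult] = None
    frequencies: Optional[FrequencyReport] = None


def _group_calls(calls) -> dict:
    if isinstance(calls, Mapping):
        return {k: list(v) for k, v in calls.items()}
    grouped: dict[tuple, list] = defaultdict(list)
    for c in calls:
        grouped[(c.sample_id, c.run_id)].append(c)
    return dict(grouped)


def run_pipeline(
    calls,
    gaps: GapTrack,
    samples: Sequence[SampleMeta],
    chrom_lengths: dict,
    pedigree: Sequence[PedigreeRecord] = (),
    genes: Sequence[AnnotationRecord] = (),
    qtl: Sequence[AnnotationRecord] = (),
    cgh_calls: Sequence[VariantCall] = (),
    snp_calls: Sequence[VariantCall] = (),
    config: PipelineConfig = PipelineConfig(),
) -> PipelineResult:
    """Run the full workflow; ``calls`` is a flat list or a
    (sample_id, run_id) -> calls mapping."""
    grouped = _group_calls(calls)
    meta_by_id = {m.sample_id: m for m in samples}

    # 1. per-run filtering
    total_report = FilterReport()
    filtered: dict[tuple, list] = {}
    for key, run_calls in sorted(grouped.items()):
        kept, rep = filter_calls(run_calls, gaps, config.filter)
        filtered[key] = kept
        for attr in ("n_input", "n_removed_gap_breakpoint",
                     "n_removed_gap_fraction", "n_removed_support",
                     "n_removed_min_size", "n_retained", "n_support_bypassed"):
            setattr(total_report, attr,
                    getattr(total_report, attr) + getattr(rep, attr))

    # 2. within-sample consensus on each sample's primary run
    consensus = []
    for m in samples:
        primary = m.run_ids[0]
        sample_calls = filtered.get((m.sample_id, primary), [])
        consensus.extend(build_consensus(sample_calls, config.consensus))
    # samples absent from metadata still flow through (primary = first run seen)
    known = {m.sample_id for m in samples}
    stray = sorted({s for (s, _r) in filtered if s not in known})
    for sid in stray:
        runs = sorted(r for (s, r) in filtered if s == sid)
        consensus.extend(build_consensus(filtered[(sid, runs[0])], config.consensus))
    if stray:
        logger.warning("calls for %d sample(s) missing from metadata: %s",
                       len(stray), stray)

    # 3. cross-sample merging
    regions = build_regions(consensus, config.region_ro)
    in_genome = [r for r in regions if r.chrom in chrom_lengths]
    if len(in_genome) < len(regions):
        logger.warning("%d region(s) on chromosomes outside the genome table "
                       "excluded from cohort reports",
                       len(regions) - len(in_genome))

    # 4. validation
    flags = {r.region_id: ValidationFlags(r.region_id) for r in regions}
    transmission = None
    mend_pct = float("nan")
    if pedigree:
        flags, transmission = mendelian_validate(
            regions, pedigree, cohort_ids=known or None, flags=flags)
        n_seen = pedigree_seen_count(regions, pedigree)
        n_mend = sum(1 for f in flags.values() if f.mendelian)
        mend_pct = mendelian_percentage(n_mend, n_seen)
    rep_calls = {
        (s, r): filtered[(s, r)]
        for (s, r) in filtered
        if s in meta_by_id and len(meta_by_id[s].run_ids) > 1
    }
    concordance = float("nan")
    if rep_calls:
        flags, concordance = replicate_validate(
            regions, rep_calls, config.replicate_ro, flags=flags)
    if cgh_calls:
        flags = external_validate(regions, cgh_calls, config.cgh_ro,
                                  flag_attr="cgh", flags=flags)
    if snp_calls:
        flags = external_validate(regions, snp_calls, config.snp_ro,
                                  flag_attr="snp_array", flags=flags)

    validated = [r for r in in_genome if flags[r.region_id].validated]

    # 5. summaries on the validated set (falling back to all regions when
    # no validation inputs were provided at all)
    has_validation = bool(pedigree or rep_calls or cgh_calls)
    report_set = validated if has_validation else in_genome
    summary = summarize_regions(report_set, samples, chrom_lengths) \
        if chrom_lengths else None
    vtable = validation_summary(in_genome, flags)
    ctable = combination_counts(report_set)

    annotation = annotate_regions(report_set, list(genes) + list(qtl)) \
        if (genes or qtl) else None
    freqs = frequency_report(report_set, samples) if samples else None

    return PipelineResult(
        filter_report=total_report,
        filtered_calls=filtered,
        consensus=consensus,
        regions=regions,
        flags=flags,
        validated_regions=validated,
        summary=summary,
        validation_table=vtable,
        combination_table=ctable,
        replicate_concordance=concordance,
        mendelian_pct=mend_pct,
        transmission_table=transmission,
        annotation=annotation,
        frequencies=freqs,
    )
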
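"""Readers and writers for on-disk pipeline artifacts.

The canonical call table is a TSV with an explicit header::

    chrom  start  end  svtype  tool  sample_id  run_id  support_reads

``start``/``end`` are 1-based inclusive, ``svtype`` is DEL or DUP and
``support_reads`` may be ``NA`` for callers that report no read count.
Columns beyond the required set are preserved as opaque annotations.
Lines starting with ``#`` are provenance/comment lines and are skipped.

BED files use the usual 0-based half-open convention; on import the start
coordinate is shifted by +1 and on export by -1 (end is unchanged).

Adapters for native caller output (CNVnator text, BreakDancer ctx, VCF
with SVTYPE/END INFO tags) are best-effort converters into the canonical
dialect; normalisation to the canonical TSV is the pre-processing contract
for everything downstream.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .core import (
    CNVRegion,
    GapTrack,
    GenomicInterval,
    IntervalError,
    SVTYPES,
    VariantCall,
)

logger = logging.getLogger("cnvcons")

__all__ = [
    "SampleMeta",
    "PedigreeRecord",
    "AnnotationRecord",
    "CallsetFormatError",
    "read_calls",
    "write_calls",
    "read_gaps",
    "write_gaps_bed",
    "read_pedigree",
    "write_pedigree",
    "read_samples",
    "write_samples",
    "read_chrom_lengths",
    "write_chrom_lengths",
    "write_regions",
    "read_regions",
    "read_features_bed",
    "read_features_gff3",
    "write_features_gff3",
    "read_cnvnator",
    "read_breakdancer",
    "read_vcf_calls",
]

CALL_COLUMNS = (
    "chrom", "start", "end", "svtype", "tool", "sample_id", "run_id",
    "support_reads",
)


class CallsetFormatError(ValueError):
    """Malformed input rows; message lists offending line numbers."""


@dataclass
class SampleMeta:
    """Cohort metadata for one animal."""

    sample_id: str
    breed: str
    breed_type: str  # dairy | beef
    coverage: float
    run_ids: list = field(default_factory=lambda: ["run1"])

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not self.run_ids:
            raise ValueError("at least one run_id is required")


@dataclass
class PedigreeRecord:
    """Offspring with at least one sequenced parent."""

    offspring_id: str
    sire_id: Optional[str] = None
    dam_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sire_id is None and self.dam_id is None:
            raise ValueError("pedigree record needs at least one parent")
        if self.offspring_id in (self.sire_id, self.dam_id):
            raise ValueError("self-parenting is not allowed")

    @property
    def parents(self) -> tuple:
        return tuple(p for p in (self.sire_id, self.dam_id) if p is not None)


@dataclass
class AnnotationRecord:
    """A gene or QTL interval used for region annotation."""

    interval: GenomicInterval
    feature_id: str
    feature_class: str  # gene | QTL
    label: str = ""  # biotype for genes, trait for QTL


def _open_rows(path):
    """Yield (lineno, raw_line) skipping comment lines."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            yield lineno, line.rstrip("\n")


# ---------------------------------------------------------------------------
# canonical call table
# ---------------------------------------------------------------------------

def read_calls(path, dialect: str = "tsv6") -> list:
    """Read VariantCall records from the canonical TSV dialect.

    ``dialect='tsv6'`` expects the full canonical header;
    ``dialect='bed6-extended'`` accepts headerless BED-style rows
    (chrom, start0, end, svtype, tool, sample[, run, support]).
    Malformed rows abort with a :class:`CallsetFormatError` naming them.
    """
    if dialect not in ("tsv6", "bed6-extended"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = list(_open_rows(path))
    calls: list[VariantCall] = []
    errors: list[str] = []

    if dialect == "tsv6":
        if not rows:
            logger.warning("call table %s is empty", path)
            return []
        header_line = rows[0][1].split("\t")
        missing = [c for c in CALL_COLUMNS if c not in header_line]
        if missing:
            raise CallsetFormatError(
                f"{path}: missing required columns {missing}"
            )
        idx = {c: header_line.index(c) for c in header_line}
        extra_cols = [c for c in header_line if c not in CALL_COLUMNS]
        body = rows[1:]
        if not body:
            logger.warning("call table %s has a header but no rows", path)
        for lineno, line in body:
            f = line.split("\t")
            try:
                if len(f) < len(header_line):
                    raise ValueError(f"expected {len(header_line)} columns, got {len(f)}")
                svtype = f[idx["svtype"]]
                if svtype not in SVTYPES:
                    raise ValueError(f"unknown svtype {svtype!r}")
                sup_raw = f[idx["support_reads"]]
                support = None if sup_raw in ("NA", "", ".") else int(sup_raw)
                call = VariantCall(
                    interval=GenomicInterval(
                        f[idx["chrom"]], int(f[idx["start"]]), int(f[idx["end"]])
                    ),
                    svtype=svtype,
                    tool=f[idx["tool"]],
                    sample_id=f[idx["sample_id"]],
                    run_id=f[idx["run_id"]],
                    support_reads=support,
                    extra={c: f[idx[c]] for c in extra_cols},
                )
            except (ValueError, IntervalError) as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            calls.append(call)
    else:  # bed6-extended, headerless, 0-based half-open start
        for lineno, line in rows:
            f = line.split("\t")
            try:
                if len(f) < 6:
                    raise ValueError("expected >= 6 columns")
                svtype = f[3]
                if svtype not in SVTYPES:
                    raise ValueError(f"unknown svtype {svtype!r}")
                support = None
                if len(f) >= 8 and f[7] not in ("NA", "", "."):
                    support = int(f[7])
                call = VariantCall(
                    interval=GenomicInterval(f[0], int(f[1]) + 1, int(f[2])),
                    svtype=svtype,
                    tool=f[4],
                    sample_id=f[5],
                    run_id=f[6] if len(f) >= 7 else "run1",
                    support_reads=support,
                )
            except (ValueError, IntervalError) as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            calls.append(call)

    if errors:
        raise CallsetFormatError(
            f"{path}: {len(errors)} malformed row(s):\n  " + "\n  ".join(errors)
        )
    return calls


def write_calls(calls: Iterable[VariantCall], path, provenance: Optional[dict] = None) -> None:
    """Write calls in the canonical TSV dialect (deterministic order)."""
    calls = sorted(
        calls, key=lambda c: (c.chrom, c.start, c.end, c.tool, c.sample_id, c.run_id)
    )
    extra_cols: list[str] = []
    for c in calls:
        for k in c.extra:
            if k not in extra_cols:
                extra_cols.append(k)
    with open(path, "w") as fh:
        _write_provenance(fh, provenance)
        fh.write("\t".join(CALL_COLUMNS + tuple(extra_cols)) + "\n")
        for c in calls:
            sup = "NA" if c.support_reads is None else str(c.support_reads)
            row = [c.chrom, str(c.start), str(c.end), c.svtype, c.tool,
                   c.sample_id, c.run_id, sup]
            row += [str(c.extra.get(k, "")) for k in extra_cols]
            fh.write("\t".join(row) + "\n")


def _write_provenance(fh, provenance: Optional[dict]) -> None:
    if provenance:
        for k, v in provenance.items():
            fh.write(f"# {k}={v}\n")


# ---------------------------------------------------------------------------
# gap track
# ---------------------------------------------------------------------------

def read_gaps(path) -> GapTrack:
    """Read an assembly gap track from BED (0-based half-open) or AGP.

    AGP rows are recognised by their 9-column layout; only component-type
    'N'/'U' (gap) rows are retained, and AGP coordinates are already
    1-based inclusive.  Input need not be sorted; gaps are coalesced.
    """
    intervals: list[GenomicInterval] = []
    for lineno, line in _open_rows(path):
        f = line.split("\t")
        if len(f) >= 9 and f[4] in ("N", "U"):  # AGP gap row
            chrom, start, end = f[0], int(f[1]), int(f[2])
        elif len(f) >= 9:
            continue  # AGP sequence component row
        elif len(f) >= 3:
            chrom, start, end = f[0], int(f[1]) + 1, int(f[2])  # BED shift
        else:
            raise CallsetFormatError(f"{path}: line {lineno}: expected >= 3 columns")
        if start < 1 or end < start:
            raise CallsetFormatError(
                f"{path}: line {lineno}: invalid gap coordinates {start}-{end}"
            )
        intervals.append(GenomicInterval(chrom, start, end))
    return GapTrack(intervals)


def write_gaps_bed(gaps: GapTrack, path) -> None:
    with open(path, "w") as fh:
        for iv in gaps:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# pedigree / sample metadata / chromosome lengths
# ---------------------------------------------------------------------------

def read_pedigree(path) -> list:
    """Read pedigree TSV with header: offspring, sire, dam (NA = unknown)."""
    rows = list(_open_rows(path))
    if not rows:
        return []
    header = rows[0][1].split("\t")
    idx = {c: header.index(c) for c in ("offspring", "sire", "dam")}
    records = []
    for lineno, line in rows[1:]:
        f = line.split("\t")
        def _opt(v):
            return None if v in ("NA", "", ".") else v
        try:
            records.append(PedigreeRecord(
                offspring_id=f[idx["offspring"]],
                sire_id=_opt(f[idx["sire"]]),
                dam_id=_opt(f[idx["dam"]]),
            ))
        except (ValueError, IndexError) as exc:
            raise CallsetFormatError(f"{path}: line {lineno}: {exc}") from exc
    return records


def write_pedigree(records: Iterable[PedigreeRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("offspring\tsire\tdam\n")
        for r in records:
            fh.write(f"{r.offspring_id}\t{r.sire_id or 'NA'}\t{r.dam_id or 'NA'}\n")


def read_samples(path) -> list:
    """Read sample metadata TSV: sample_id, breed, breed_type, coverage, run_ids."""
    rows = list(_open_rows(path))
    if not rows:
        return []
    header = rows[0][1].split("\t")
    idx = {c: header.index(c)
           for c in ("sample_id", "breed", "breed_type", "coverage", "run_ids")}
    metas = []
    for lineno, line in rows[1:]:
        f = line.split("\t")
        try:
            metas.append(SampleMeta(
                sample_id=f[idx["sample_id"]],
                breed=f[idx["breed"]],
                breed_type=f[idx["breed_type"]],
                coverage=float(f[idx["coverage"]]),
                run_ids=f[idx["run_ids"]].split(","),
            ))
        except (ValueError, IndexError) as exc:
            raise CallsetFormatError(f"{path}: line {lineno}: {exc}") from exc
    return metas


def write_samples(metas: Iterable[SampleMeta], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tbreed\tbreed_type\tcoverage\trun_ids\n")
        for m in metas:
            fh.write(f"{m.sample_id}\t{m.breed}\t{m.breed_type}\t"
                     f"{m.coverage:g}\t{','.join(m.run_ids)}\n")


def read_chrom_lengths(path) -> dict:
    lengths = {}
    for _, line in _open_rows(path):
        f = line.split("\t")
        if f[0] == "chrom":
            continue
        lengths[f[0]] = int(f[1])
    return lengths


def write_chrom_lengths(lengths: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tlength\n")
        for chrom, n in lengths.items():
            fh.write(f"{chrom}\t{n}\n")


# ---------------------------------------------------------------------------
# region reports
# ---------------------------------------------------------------------------

REGION_COLUMNS = (
    "region_id", "chrom", "start", "end", "size", "region_type",
    "n_carriers", "carriers", "tools",
)


def write_regions(regions: Sequence[CNVRegion], path,
                  sample_meta: Optional[Sequence[SampleMeta]] = None,
                  provenance: Optional[dict] = None) -> None:
    """Write the region report TSV plus a companion BED track.

    Output is sorted by (chrom, start) regardless of input order.  When
    sample metadata is supplied a ``breeds`` column lists the carrier
    breeds.  The BED track is written next to ``path`` with a ``.bed``
    suffix.
    """
    path = Path(path)
    regions = sorted(regions, key=lambda r: (r.chrom, r.start, r.end))
    breed_of = {m.sample_id: m.breed for m in sample_meta or ()}
    cols = list(REGION_COLUMNS)
    if sample_meta is not None:
        cols.append("breeds")
    with open(path, "w") as fh:
        _write_provenance(fh, provenance)
        fh.write("\t".join(cols) + "\n")
        for r in regions:
            row = [r.region_id, r.chrom, str(r.start), str(r.end), str(r.size),
                   r.region_type, str(len(r.carriers)),
                   ",".join(sorted(r.carriers)),
                   ",".join(sorted(r.tools)) or "NA"]
            if sample_meta is not None:
                breeds = sorted({breed_of[s] for s in r.carriers if s in breed_of})
                row.append(",".join(breeds) or "NA")
            fh.write("\t".join(row) + "\n")
    with open(path.with_suffix(".bed"), "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t"
                     f"{r.region_id}|{r.region_type}\n")


def read_regions(path) -> list:
    """Read a region report written by :func:`write_regions`.

    Members are not reconstructed (the report is a summary); carriers and
    tool lists round-trip.
    """
    rows = list(_open_rows(path))
    if not rows:
        return []
    header = rows[0][1].split("\t")
    idx = {c: header.index(c) for c in REGION_COLUMNS if c in header}
    regions = []
    for lineno, line in rows[1:]:
        f = line.split("\t")
        tools = f[idx["tools"]]
        r = CNVRegion(
            interval=GenomicInterval(f[idx["chrom"]], int(f[idx["start"]]),
                                     int(f[idx["end"]])),
            region_type=f[idx["region_type"]],
            members=[],
            carriers=frozenset(f[idx["carriers"]].split(","))
            if f[idx["carriers"]] else frozenset(),
            region_id=f[idx["region_id"]],
        )
        r.extra_tools = frozenset() if tools == "NA" else frozenset(tools.split(","))  # type: ignore[attr-defined]
        regions.append(r)
    return regions


# ---------------------------------------------------------------------------
# consensus variant tables
# ---------------------------------------------------------------------------

CONSENSUS_COLUMNS = (
    "chrom", "start", "end", "svtype", "sample_id", "tools", "tool_pairs",
)


def write_consensus(variants, path, provenance: Optional[dict] = None) -> None:
    """Write consensus variants with their tool list and matched pairs.

    Source calls are not serialised (the table is the hand-off to the
    cross-sample merge, which operates on spans only).
    """
    variants = sorted(variants, key=lambda v: (v.chrom, v.start, v.end,
                                               v.svtype, v.sample_id))
    with open(path, "w") as fh:
        _write_provenance(fh, provenance)
        fh.write("\t".join(CONSENSUS_COLUMNS) + "\n")
        for v in variants:
            pairs = ";".join(sorted("+".join(sorted(p)) for p in v.tool_pairs))
            fh.write(f"{v.chrom}\t{v.start}\t{v.end}\t{v.svtype}\t"
                     f"{v.sample_id}\t{','.join(sorted(v.tools))}\t{pairs}\n")


def read_consensus(path) -> list:
    from .core import ConsensusVariant

    rows = list(_open_rows(path))
    if not rows:
        return []
    header = rows[0][1].split("\t")
    idx = {c: header.index(c) for c in CONSENSUS_COLUMNS}
    out = []
    for lineno, line in rows[1:]:
        f = line.split("\t")
        pairs = frozenset(
            frozenset(p.split("+")) for p in f[idx["tool_pairs"]].split(";") if p
        )
        out.append(ConsensusVariant(
            interval=GenomicInterval(f[idx["chrom"]], int(f[idx["start"]]),
                                     int(f[idx["end"]])),
            svtype=f[idx["svtype"]],
            sample_id=f[idx["sample_id"]],
            tools=frozenset(f[idx["tools"]].split(",")),
            source_calls=[],
            tool_pairs=pairs,
        ))
    return out


# ---------------------------------------------------------------------------
# annotation features
# ---------------------------------------------------------------------------

def read_features_bed(path, feature_class: str = "QTL") -> list:
    """Read features from BED; column 4 (name) becomes feature_id, column 5
    (if present) the trait/biotype label."""
    feats = []
    for lineno, line in _open_rows(path):
        f = line.split("\t")
        if len(f) < 3:
            raise CallsetFormatError(f"{path}: line {lineno}: expected >= 3 columns")
        fid = f[3] if len(f) >= 4 else f"{feature_class}_{lineno}"
        label = f[4] if len(f) >= 5 else ""
        feats.append(AnnotationRecord(
            interval=GenomicInterval(f[0], int(f[1]) + 1, int(f[2])),
            feature_id=fid, feature_class=feature_class, label=label,
        ))
    return feats


def read_features_gff3(path, feature_type: str = "gene") -> list:
    """Read gene features from GFF3 via gffutils (in-memory db)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    feats = []
    for g in db.features_of_type(feature_type, order_by=("seqid", "start")):
        fid = g.id
        biotype = (g.attributes.get("biotype") or g.attributes.get("gene_biotype")
                   or [""])[0]
        feats.append(AnnotationRecord(
            interval=GenomicInterval(g.seqid, g.start, g.end),
            feature_id=fid, feature_class="gene", label=biotype,
        ))
    return feats


def write_features_gff3(feats: Iterable[AnnotationRecord], path,
                        source: str = "cnvcons") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            ftype = "gene" if f.feature_class == "gene" else "region"
            attrs = f"ID={f.feature_id}"
            if f.label:
                attrs += f";biotype={f.label}"
            fh.write(f"{f.interval.chrom}\t{source}\t{ftype}\t{f.interval.start}\t"
                     f"{f.interval.end}\t.\t.\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# native caller adapters (best-effort converters to the canonical dialect)
# ---------------------------------------------------------------------------

def read_cnvnator(path, sample_id: str, run_id: str = "run1") -> list:
    """Adapter for CNVnator text output.

    Expected columns: call_type (deletion/duplication), coordinates
    (chrom:start-end), size, normalized read depth, then e-values.
    CNVnator reports read-depth windows, not supporting reads, so
    ``support_reads`` is ``None``.
    """
    calls = []
    for lineno, line in _open_rows(path):
        f = line.split("\t")
        kind = f[0].lower()
        if kind.startswith("del"):
            svtype = "DEL"
        elif kind.startswith("dup"):
            svtype = "DUP"
        else:
            logger.info("cnvnator adapter: skipping %s row at line %d", f[0], lineno)
            continue
        chrom, span = f[1].split(":")
        start, end = (int(x) for x in span.split("-"))
        calls.append(VariantCall(
            interval=GenomicInterval(chrom, start, end), svtype=svtype,
            tool="cnvnator", sample_id=sample_id, run_id=run_id,
            support_reads=None,
            extra={"norm_rd": f[3]} if len(f) > 3 else {},
        ))
    return calls


def read_breakdancer(path, sample_id: str, run_id: str = "run1") -> list:
    """Adapter for BreakDancer ctx output.

    Columns: chr1 pos1 ori1 chr2 pos2 ori2 type size score num_reads.
    Only intra-chromosomal DEL rows map to deletions; ITX/CTX/INV/INS rows
    are skipped with a logged count.
    """
    calls = []
    skipped = 0
    for lineno, line in _open_rows(path):
        f = line.split("\t")
        if len(f) < 10:
            raise CallsetFormatError(f"{path}: line {lineno}: expected >= 10 columns")
        svt = f[6].upper()
        if svt == "DEL" and f[0] == f[3]:
            svtype = "DEL"
        elif svt in ("DUP", "TDUP", "ITX") and f[0] == f[3] and svt != "ITX":
            svtype = "DUP"
        else:
            skipped += 1
            continue
        start, end = int(f[1]), int(f[4])
        if end < start:
            start, end = end, start
        calls.append(VariantCall(
            interval=GenomicInterval(f[0], start, end), svtype=svtype,
            tool="breakdancer", sample_id=sample_id, run_id=run_id,
            support_reads=int(f[9]),
        ))
    if skipped:
        logger.info("breakdancer adapter: skipped %d non-DEL/DUP rows", skipped)
    return calls


def read_vcf_calls(path, tool: str, sample_id: Optional[str] = None,
                   run_id: str = "run1") -> list:
    """Adapter for VCF with SVTYPE and END INFO tags (e.g. DELLY, Pindel).

    Records whose SVTYPE is not DEL or DUP are skipped with a logged
    count.  Supporting reads are taken from the PE/SR/DV INFO or FORMAT
    fields if present (summed PE+SR), else ``None``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if sample_id is None:
        sample_id = vcf.samples[0] if vcf.samples else "unknown"
    calls = []
    skipped = 0
    for rec in vcf:
        svtype = rec.INFO.get("SVTYPE")
        if svtype not in SVTYPES:
            skipped += 1
            continue
        end = rec.INFO.get("END") or rec.end
        support = None
        pe = rec.INFO.get("PE")
        sr = rec.INFO.get("SR")
        if pe is not None or sr is not None:
            support = int(pe or 0) + int(sr or 0)
        calls.append(VariantCall(
            interval=GenomicInterval(rec.CHROM, rec.POS, int(end)),
            svtype=svtype, tool=tool, sample_id=sample_id, run_id=run_id,
            support_reads=support,
        ))
    if skipped:
        logger.info("vcf adapter: skipped %d non-DEL/DUP records", skipped)
    return calls
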
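"""Synthetic cohort, truth-CNV and caller-output generator.

Generates every input the pipeline consumes — a genome with assembly
gaps, a cohort with breeds, pedigree and replicate sequencing runs, true
CNV loci with population frequencies, and noisy per-tool call sets — so
the whole workflow can run and be scored at desk scale.

The emulated study design follows a 200-animal, 8-breed cattle cohort
sequenced at 8-33x with two sire-dam-son trios, 16 sire-son pairs and 14
twice-sequenced animals (the ``study`` preset); the ``demo`` preset is a
20-animal, 2-chromosome miniature of the same structure.  True deletion
and duplication sizes are log-normal, calibrated so that deletion sizes
have median ~1.5 kb with upper quartile ~3.3 kb and duplication sizes
median ~8.7 kb with lower quartile ~4.4 kb.

Caller emulation is phenomenological: each tool detects a carried locus
with its sensitivity, jitters breakpoints with Gaussian noise,
read-depth-style tools snap breakpoints to a 250-bp window grid, and
false positives arrive as a Poisson process per Mb.  No read-level or
sequence-level structure is simulated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import GapTrack, GenomicInterval, VariantCall
from .io import (
    AnnotationRecord,
    PedigreeRecord,
    SampleMeta,
    write_calls,
    write_chrom_lengths,
    write_features_gff3,
    write_gaps_bed,
    write_pedigree,
    write_samples,
)

logger = logging.getLogger("cnvcons")

__all__ = [
    "CallerProfile",
    "SimConfig",
    "TrueLocus",
    "Truth",
    "default_profiles",
    "noiseless_profiles",
    "simulate_truth",
    "emulate_callers",
    "write_fixture_bundle",
    "read_truth_manifest",
]

# log-normal size parameters: median = exp(mu); sigma chosen so the
# quartiles match the calibration targets (Q3(del) ~ 3.3 kb, Q1(dup) ~ 4.4 kb)
_DEL_MU, _DEL_SIGMA = float(np.log(1500.0)), 1.17
_DUP_MU, _DUP_SIGMA = float(np.log(8700.0)), 1.01
_Z75 = 0.6744897501960817  # standard normal upper quartile


@dataclass(frozen=True)
class CallerProfile:
    """Behavioural parameters of one emulated CNV caller.

    ``support_model`` is (intercept, slope): mean supporting reads =
    intercept + slope * coverage, drawn Poisson; ``None`` means the tool
    reports no read count (read-depth callers report windows).
    ``rd_window`` snaps breakpoints outward to a window grid for
    RD-style tools; ``None`` disables snapping.
    """

    name: str
    style: str  # RD | PEM | SR
    sensitivity: float = 0.8
    fp_per_mb: float = 0.1
    jitter_sd: float = 50.0
    support_model: Optional[tuple] = (1.0, 0.5)
    rd_window: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must be in [0, 1]")
        if self.fp_per_mb < 0 or self.jitter_sd < 0:
            raise ValueError("fp_per_mb and jitter_sd must be >= 0")
        if self.style not in ("RD", "PEM", "SR"):
            raise ValueError("style must be RD, PEM or SR")


def default_profiles() -> tuple:
    """Profiles emulating the four-caller design.

    Sensitivities and false-positive rates are stylised: the PEM caller
    pair is generous but noisy (emulating the high-discovery /
    high-false-positive behaviour reported for paired-end tools), the
    split-read callers are precise with tight breakpoints, and the RD
    caller has window-grid resolution and no read-count column.
    """
    return (
        CallerProfile("cnvnator", "RD", sensitivity=0.80, fp_per_mb=0.10,
                      jitter_sd=0.0, support_model=None, rd_window=250),
        CallerProfile("breakdancer", "PEM", sensitivity=0.85, fp_per_mb=0.20,
                      jitter_sd=60.0, support_model=(1.0, 0.5)),
        CallerProfile("pindel", "SR", sensitivity=0.70, fp_per_mb=0.05,
                      jitter_sd=10.0, support_model=(1.0, 0.4)),
        CallerProfile("delly", "SR", sensitivity=0.85, fp_per_mb=0.15,
                      jitter_sd=15.0, support_model=(1.0, 0.5)),
    )


def noiseless_profiles(sensitivity: float = 1.0) -> tuple:
    """Four tools with zero jitter, no false positives, no grid snapping
    and abundant support — the exact-recovery limit."""
    return tuple(
        CallerProfile(name, style, sensitivity=sensitivity, fp_per_mb=0.0,
                      jitter_sd=0.0, support_model=(30.0, 0.0), rd_window=None)
        for name, style in (("cnvnator", "RD"), ("breakdancer", "PEM"),
                            ("pindel", "SR"), ("delly", "SR"))
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the simulator.

    Defaults are the demo scale; :meth:`study` mirrors the full cohort
    design (200 animals in 8 breeds, 2 trios, 16 sire-son pairs, 14
    twice-sequenced animals, coverage 8-33x).  ``breeds`` maps breed name
    to (n_animals, breed_type, cov_min, cov_max).  ``transmission_prob``
    is the per-parent probability that an offspring inherits a carried
    locus.
    """

    seed: int = 0
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000})
    breeds: Mapping[str, tuple] = field(default_factory=lambda: {
        "Holstein": (7, "dairy", 8, 21),
        "Montbeliarde": (5, "dairy", 9, 28),
        "Charolaise": (5, "beef", 11, 25),
        "Limousine": (3, "beef", 8, 25),
    })
    n_trios: int = 1
    n_pairs: int = 4
    n_replicate_animals: int = 2
    n_del_loci: int = 180
    n_dup_loci: int = 20
    del_size: tuple = (_DEL_MU, _DEL_SIGMA)
    dup_size: tuple = (_DUP_MU, _DUP_SIGMA)
    gap_per_mb: float = 0.5
    gap_size: tuple = (float(np.log(1000.0)), 1.0)
    p_rare: float = 0.5
    rare_freq: tuple = (0.005, 0.05)
    common_freq: tuple = (0.10, 0.97)
    transmission_prob: float = 0.5
    min_size: int = 50
    placement_margin: int = 150  # keep loci clear of gap windows
    genes_per_mb: float = 10.0
    qtl_per_mb: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.transmission_prob <= 1.0:
            raise ValueError("transmission_prob must be in [0, 1]")
        if self.n_del_loci < 0 or self.n_dup_loci < 0:
            raise ValueError("locus counts must be >= 0")

    @property
    def n_animals(self) -> int:
        return sum(b[0] for b in self.breeds.values())

    @classmethod
    def demo(cls, seed: int = 0) -> "SimConfig":
        """2 chromosomes x 5 Mb, 20 animals, 200 loci."""
        return cls(seed=seed)

    @classmethod
    def study(cls, seed: int = 0, scale_mb: float = 100.0) -> "SimConfig":
        """The full cohort design on a scaled genome.

        29 autosomes with linearly decreasing lengths totalling
        ``scale_mb`` megabases (default 100 Mb; the real autosomal genome
        is ~2500 Mb — locus counts are scaled accordingly to keep locus
        density realistic while staying fast).
        """
        raw = np.linspace(158.0, 42.0, 29)
        raw *= scale_mb / raw.sum()
        chroms = {f"chr{i + 1}": int(round(raw[i] * 1e6)) for i in range(29)}
        frac = scale_mb / 2500.0
        return cls(
            seed=seed,
            chrom_lengths=chroms,
            breeds={
                "BlondeAquitaine": (25, "beef", 11, 26),
                "BrownSwiss": (3, "dairy", 9, 12),
                "Charolaise": (25, "beef", 11, 25),
                "Holstein": (56, "dairy", 8, 21),
                "Limousine": (34, "beef", 8, 25),
                "Montbeliarde": (31, "dairy", 9, 28),
                "Normande": (23, "dairy", 8, 33),
                "RougeDesPres": (3, "beef", 16, 31),
            },
            n_trios=2,
            n_pairs=16,
            n_replicate_animals=14,
            n_del_loci=max(1, int(round(19000 * 0.94 * frac))),
            n_dup_loci=max(1, int(round(19000 * 0.06 * frac))),
        )


@dataclass(frozen=True)
class TrueLocus:
    locus_id: str
    interval: GenomicInterval
    svtype: str
    freq: float


@dataclass
class Truth:
    """Ground truth bundle: everything the pipeline's inputs derive from."""

    config: SimConfig
    gaps: GapTrack
    samples: list  # SampleMeta
    pedigree: list  # PedigreeRecord
    loci: list  # TrueLocus
    carriers: dict  # sample_id -> frozenset of locus_id
    genes: list  # AnnotationRecord
    qtl: list  # AnnotationRecord

    @property
    def chrom_lengths(self) -> dict:
        return dict(self.config.chrom_lengths)

    def carried_loci(self) -> dict:
        """locus_id -> set of carrier sample_ids (only loci with carriers)."""
        out: dict[str, set] = {}
        for sid, ids in self.carriers.items():
            for lid in ids:
                out.setdefault(lid, set()).add(sid)
        return out


# ---------------------------------------------------------------------------
# truth simulation
# ---------------------------------------------------------------------------

def _sample_sizes(rng, mu: float, sigma: float, n: int, min_size: int) -> np.ndarray:
    sizes = np.exp(rng.normal(mu, sigma, size=n))
    return np.maximum(np.round(sizes).astype(np.int64), min_size)


def _place_gaps(rng, config: SimConfig) -> GapTrack:
    gaps = []
    mu, sigma = config.gap_size
    for chrom, length in config.chrom_lengths.items():
        n = rng.poisson(config.gap_per_mb * length / 1e6)
        for _ in range(n):
            size = int(max(50, round(np.exp(rng.normal(mu, sigma)))))
            start = int(rng.integers(1, max(2, length - size)))
            gaps.append(GenomicInterval(chrom, start, min(start + size - 1, length)))
    return GapTrack(gaps)


def _place_loci(rng, config: SimConfig, gaps: GapTrack) -> list:
    """Place non-overlapping truth loci clear of gaps (with margin)."""
    import bisect

    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    occupied: dict[str, list] = {c: [] for c in chroms}  # sorted (start, end)

    specs = [("DEL", config.del_size)] * config.n_del_loci + \
            [("DUP", config.dup_size)] * config.n_dup_loci
    loci = []
    margin = config.placement_margin
    for k, (svtype, (mu, sigma)) in enumerate(specs):
        # size drawn once per locus: re-drawing on every placement retry
        # would bias the accepted size distribution toward small events.
        # A stuck locus (huge tail draw in a crowded genome) re-draws its
        # size only after many failed position attempts.
        size = int(_sample_sizes(rng, mu, sigma, 1, config.min_size)[0])
        placed = False
        tries = 0
        while not placed:
            tries += 1
            if tries > 2000:
                raise ValueError(
                    "could not place all truth loci without overlap; reduce "
                    "locus counts or size medians, or enlarge chrom_lengths"
                )
            if tries % 100 == 0:
                size = int(_sample_sizes(rng, mu, sigma, 1, config.min_size)[0])
            ci = rng.choice(len(chroms), p=weights)
            chrom = chroms[ci]
            L = config.chrom_lengths[chrom]
            if size + 2 * margin >= L:
                size = int(_sample_sizes(rng, mu, sigma, 1, config.min_size)[0])
                continue
            start = int(rng.integers(1 + margin, L - size - margin))
            end = start + size - 1
            # clear of gaps (including the breakpoint window margin)?
            if gaps.any_gap_in(chrom, start - margin, end + margin):
                continue
            # non-overlapping with already placed loci (with margin so
            # distinct loci never merge spuriously at 70% RO)
            occ = occupied[chrom]
            i = bisect.bisect_left(occ, (start, end))
            if i > 0 and occ[i - 1][1] + margin >= start:
                continue
            if i < len(occ) and occ[i][0] - margin <= end:
                continue
            occ.insert(i, (start, end))
            loci.append((chrom, start, end, svtype))
            placed = True
    loci.sort()
    return [
        TrueLocus(f"LOC_{i + 1:05d}", GenomicInterval(c, s, e), t, 0.0)
        for i, (c, s, e, t) in enumerate(loci)
    ]


def _build_cohort(rng, config: SimConfig) -> tuple:
    samples: list[SampleMeta] = []
    for breed, (n, btype, cov_lo, cov_hi) in config.breeds.items():
        for i in range(n):
            samples.append(SampleMeta(
                sample_id=f"{breed[:3].upper()}_{i + 1:03d}",
                breed=breed,
                breed_type=btype,
                coverage=float(np.round(rng.uniform(cov_lo, cov_hi), 1)),
                run_ids=["run1"],
            ))

    # pedigree: trios and sire-son pairs drawn from dairy animals first
    # (the real design used dairy trios/pairs), falling back to any breed
    dairy = [s for s in samples if s.breed_type == "dairy"]
    others = [s for s in samples if s.breed_type == "beef"]
    pool = dairy + others
    need = 3 * config.n_trios + 2 * config.n_pairs
    if need > len(pool):
        raise ValueError("not enough animals for the requested pedigree")
    chosen = [pool[i] for i in range(need)]
    pedigree: list[PedigreeRecord] = []
    k = 0
    for _ in range(config.n_trios):
        sire, dam, son = chosen[k], chosen[k + 1], chosen[k + 2]
        pedigree.append(PedigreeRecord(son.sample_id, sire.sample_id, dam.sample_id))
        k += 3
    for _ in range(config.n_pairs):
        sire, son = chosen[k], chosen[k + 1]
        pedigree.append(PedigreeRecord(son.sample_id, sire.sample_id))
        k += 2

    # twice-sequenced animals: prefer non-offspring so replicate and
    # Mendelian structure stay independent
    offspring = {p.offspring_id for p in pedigree}
    candidates = [s for s in samples if s.sample_id not in offspring]
    if config.n_replicate_animals > len(candidates):
        raise ValueError("not enough animals for the requested replicates")
    idx = rng.choice(len(candidates), size=config.n_replicate_animals,
                     replace=False)
    for i in sorted(idx):
        candidates[i].run_ids = ["run1", "run2"]
    return samples, pedigree


def _assign_carriers(rng, config: SimConfig, loci: list, samples: list,
                     pedigree: list) -> tuple:
    """Founder Bernoulli draws; offspring inherit from carrier parents."""
    freqs = np.where(
        rng.random(len(loci)) < config.p_rare,
        rng.uniform(*config.rare_freq, size=len(loci)),
        rng.uniform(*config.common_freq, size=len(loci)),
    )
    loci = [replace(l, freq=float(f)) for l, f in zip(loci, freqs)]

    offspring_of = {p.offspring_id: p for p in pedigree}
    carriers: dict[str, set] = {s.sample_id: set() for s in samples}
    founders = [s.sample_id for s in samples if s.sample_id not in offspring_of]
    for locus in loci:
        draws = rng.random(len(founders)) < locus.freq
        for sid, hit in zip(founders, draws):
            if hit:
                carriers[sid].add(locus.locus_id)
    # offspring: inherit each parent-carried locus with transmission_prob;
    # no de novo events (idealised Mendelian structure)
    for rec in pedigree:
        inherited = set()
        for parent in rec.parents:
            for lid in carriers.get(parent, ()):
                if rng.random() < config.transmission_prob:
                    inherited.add(lid)
        carriers[rec.offspring_id] = inherited
    return loci, {k: frozenset(v) for k, v in carriers.items()}


def _place_features(rng, config: SimConfig) -> tuple:
    genes, qtl = [], []
    gi = qi = 0
    for chrom, length in config.chrom_lengths.items():
        n_genes = rng.poisson(config.genes_per_mb * length / 1e6)
        for _ in range(n_genes):
            size = int(max(200, round(np.exp(rng.normal(np.log(15000.0), 1.0)))))
            start = int(rng.integers(1, max(2, length - size)))
            gi += 1
            genes.append(AnnotationRecord(
                GenomicInterval(chrom, start, min(start + size - 1, length)),
                f"GENE_{gi:05d}", "gene", "protein_coding"))
        n_qtl = rng.poisson(config.qtl_per_mb * length / 1e6)
        traits = ("milk", "production", "health", "reproduction", "meat")
        for _ in range(n_qtl):
            size = int(rng.integers(200_000, 2_000_000))
            start = int(rng.integers(1, max(2, length - size)))
            qi += 1
            qtl.append(AnnotationRecord(
                GenomicInterval(chrom, start, min(start + size - 1, length)),
                f"QTL_{qi:05d}", "QTL", traits[int(rng.integers(len(traits)))]))
    key = lambda f: (f.interval.chrom, f.interval.start, f.interval.end)
    return sorted(genes, key=key), sorted(qtl, key=key)


def simulate_truth(config: SimConfig) -> Truth:
    """Simulate gaps, cohort, pedigree, truth loci and carrier status.

    Fully deterministic for a fixed config (including seed).
    """
    rng = np.random.default_rng([config.seed, 1])
    gaps = _place_gaps(rng, config)
    samples, pedigree = _build_cohort(rng, config)
    loci = _place_loci(rng, config, gaps)
    loci, carriers = _assign_carriers(rng, config, loci, samples, pedigree)
    genes, qtl = _place_features(rng, config)
    return Truth(config=config, gaps=gaps, samples=samples, pedigree=pedigree,
                 loci=loci, carriers=carriers, genes=genes, qtl=qtl)


# ---------------------------------------------------------------------------
# caller emulation
# ---------------------------------------------------------------------------

def _snap_rd(start: int, end: int, window: int) -> tuple:
    start = ((start - 1) // window) * window + 1
    end = ((end + window - 1) // window) * window
    return start, end


def emulate_callers(
    truth: Truth,
    profiles: Sequence[CallerProfile] = None,
    seed: Optional[int] = None,
) -> dict:
    """Generate per-(sample, run) noisy call lists from the truth.

    Each tool detects each carried locus with its sensitivity, jitters
    both breakpoints independently (normal, sd = ``jitter_sd``; RD-style
    tools then snap outward to the window grid), and draws supporting
    reads from Poisson(intercept + slope * coverage).  False positives
    are a Poisson process at ``fp_per_mb`` per megabase with random type
    and sizes from that type's distribution.  Replicate runs redraw all
    noise independently from the same truth.

    Returns ``{(sample_id, run_id): [VariantCall, ...]}``.
    """
    if profiles is None:
        profiles = default_profiles()
    if len(profiles) < 2:
        raise ValueError("caller emulation needs >= 2 tool profiles")
    config = truth.config
    rng = np.random.default_rng(
        [config.seed if seed is None else seed, 2])
    loci_by_id = {l.locus_id: l for l in truth.loci}
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    genome_mb = lengths.sum() / 1e6

    out: dict[tuple, list] = {}
    for meta in truth.samples:
        carried = sorted(truth.carriers.get(meta.sample_id, ()))
        for run_id in meta.run_ids:
            calls: list[VariantCall] = []
            for prof in profiles:
                for lid in carried:
                    if rng.random() >= prof.sensitivity:
                        continue
                    locus = loci_by_id[lid]
                    s, e = locus.interval.start, locus.interval.end
                    if prof.jitter_sd > 0:
                        s = s + int(round(rng.normal(0, prof.jitter_sd)))
                        e = e + int(round(rng.normal(0, prof.jitter_sd)))
                    if prof.rd_window:
                        s, e = _snap_rd(s, e, prof.rd_window)
                    s = max(1, s)
                    e = max(s, e)
                    calls.append(VariantCall(
                        interval=GenomicInterval(locus.interval.chrom, s, e),
                        svtype=locus.svtype,
                        tool=prof.name,
                        sample_id=meta.sample_id,
                        run_id=run_id,
                        support_reads=_draw_support(rng, prof, meta.coverage),
                        extra={"truth_id": lid},
                    ))
                n_fp = rng.poisson(prof.fp_per_mb * genome_mb)
                for _ in range(n_fp):
                    svtype = "DEL" if rng.random() < 0.9 else "DUP"
                    mu, sigma = config.del_size if svtype == "DEL" else config.dup_size
                    size = int(_sample_sizes(rng, mu, sigma, 1, config.min_size)[0])
                    ci = rng.choice(len(chroms), p=weights)
                    chrom = chroms[ci]
                    L = config.chrom_lengths[chrom]
                    if size >= L:
                        continue
                    s = int(rng.integers(1, L - size))
                    iv = GenomicInterval(chrom, s, s + size - 1)
                    if prof.rd_window:
                        gs, ge = _snap_rd(iv.start, iv.end, prof.rd_window)
                        iv = GenomicInterval(chrom, max(1, gs), max(gs, ge))
                    calls.append(VariantCall(
                        interval=iv, svtype=svtype, tool=prof.name,
                        sample_id=meta.sample_id, run_id=run_id,
                        support_reads=_draw_support(rng, prof, meta.coverage),
                        extra={"truth_id": "FP"},
                    ))
            out[(meta.sample_id, run_id)] = calls
    return out


def _draw_support(rng, prof: CallerProfile, coverage: float) -> Optional[int]:
    if prof.support_model is None:
        return None
    intercept, slope = prof.support_model
    return int(rng.poisson(max(0.0, intercept + slope * coverage)))


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(truth: Truth, calls: Mapping[tuple, Sequence], outdir) -> dict:
    """Write all pipeline inputs plus a truth manifest; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "calls": outdir / "calls.tsv",
        "gaps": outdir / "gaps.bed",
        "samples": outdir / "samples.tsv",
        "pedigree": outdir / "pedigree.tsv",
        "chrom_lengths": outdir / "chrom_lengths.tsv",
        "genes": outdir / "genes.gff3",
        "qtl": outdir / "qtl.bed",
        "truth": outdir / "truth.tsv",
    }
    flat = [c for lst in calls.values() for c in lst]
    write_calls(flat, paths["calls"],
                provenance={"generator": "cnvcons-simulate",
                            "seed": truth.config.seed})
    write_gaps_bed(truth.gaps, paths["gaps"])
    write_samples(truth.samples, paths["samples"])
    write_pedigree(truth.pedigree, paths["pedigree"])
    write_chrom_lengths(truth.chrom_lengths, paths["chrom_lengths"])
    write_features_gff3(truth.genes, paths["genes"])
    with open(paths["qtl"], "w") as fh:
        for q in truth.qtl:
            fh.write(f"{q.interval.chrom}\t{q.interval.start - 1}\t"
                     f"{q.interval.end}\t{q.feature_id}\t{q.label}\n")
    carried = truth.carried_loci()
    with open(paths["truth"], "w") as fh:
        fh.write("locus_id\tchrom\tstart\tend\tsvtype\tfreq\tcarriers\n")
        for l in truth.loci:
            cs = ",".join(sorted(carried.get(l.locus_id, ())))
            fh.write(f"{l.locus_id}\t{l.interval.chrom}\t{l.interval.start}\t"
                     f"{l.interval.end}\t{l.svtype}\t{l.freq:.6f}\t{cs}\n")
    return paths


def read_truth_manifest(path) -> tuple:
    """Read back the truth manifest: (loci, locus_id -> carrier set)."""
    loci = []
    carriers: dict[str, set] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            loci.append(TrueLocus(
                f[0], GenomicInterval(f[1], int(f[2]), int(f[3])), f[4],
                float(f[5])))
            carriers[f[0]] = set(f[6].split(",")) if f[6] else set()
    return loci, carriers
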
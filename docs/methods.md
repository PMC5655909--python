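# Methods

## Coordinate and size conventions

All in-memory coordinates are 1-based inclusive; an interval of length
L spans `start .. start + L - 1` and `length = end - start + 1`.  This
matches how CNV sizes are conventionally printed (a 334-bp variant has
`end - start + 1 = 334`).  BED input/output shifts the start coordinate
by exactly one; AGP gap rows are already 1-based and are used as-is.
Reciprocal overlap of intervals a and b is
`min(|a∩b|/|a|, |a∩b|/|b|)` with `|a∩b|` counted in whole bases; it is
0 across chromosomes and for adjacent intervals, and 1 only for
identical intervals.

## Filtering

Four per-call rules run in a fixed order — gap-at-breakpoint, gap
content, read support, minimum size — and each removed call is charged
to the first rule it fails, so the removal accounting is deterministic
and partitions the input.  The order itself is a reporting convention;
the retained set is order-independent because a call is kept only if it
fails no rule.

* The gap-at-breakpoint test asks whether any gap base lies within a
  symmetric window (default 100 bp) of either breakpoint.  Applying the
  window per breakpoint rather than to the union span is a
  design choice; both readings are expressible (the union span is the
  per-breakpoint test with a window of half the call length), and the
  window is a config knob.
* Gap content uses a strict inequality: a call is dropped only when
  *more than* 25% of its bases are gap sequence; exactly 25% survives.
* Calls that carry no supporting-read count (read-depth callers report
  windows, not reads) bypass the support rule and are counted
  separately in the report.
* The 50-bp size floor is the conventional lower bound of the CNV
  definition; it is configurable because merged real datasets often
  have larger effective minima.

## Within-sample consensus

Calls of the same type within a sample are nodes of a graph with an
edge wherever the tool-pair rule holds: breakpoints within 100 bp for
the designated split-read pair (default pindel + delly), otherwise
RO ≥ 0.90.  The breakpoint rule *replaces* RO for that pair — two short
calls can match on breakpoints while overlapping much less than 90% — a
`strict_bp_pair` flag requires both criteria instead.  Consensus
variants are the connected components with ≥ 2 distinct tools
(single-linkage closure; a `clique_mode` option additionally demands
that every cross-tool pair inside the component matches).  The
consensus interval is the union span of members, consistent with the
min/max rule used at the region level.  Deletions and duplications
never merge at this stage; the two types meet only when regions are
formed.

## Cross-sample regions

Consensus variants on one chromosome, from any sample and of either
type, cluster by single linkage at RO ≥ 0.70, with the extra
requirement of at least one shared base (so a threshold of 0 merges
exactly the touching intervals).  Single linkage is the only closure
consistent with merging "across all samples" given purely pairwise
rules, and it can chain: regions can end up far larger than any member
(multi-megabase regions arise this way in real cohorts).  Each cluster
becomes one region spanning min-start .. max-end, typed deletion-only /
duplication-only / CNVR by its member types; singletons are kept as
singleton regions because unique single-sample variants are a reported
quantity, not noise.  Region ids are zero-padded sequential in
(chromosome, start) order and are an artifact of the run.

Carrier sets are sample-id based: a twice-sequenced animal counts once.
Only one run per animal (the first listed run id) contributes calls to
consensus and region construction; replicate runs exist solely for the
recurrence check below.

## Validation

A region in the final retained set is **validated** when it passes
Mendelian transmission OR replicate recurrence OR array-CGH matching;
SNP-array support is a recorded confirmation column, not a retaining
criterion.  Rationale: the retained set in this design is defined by
the union of the two in-silico strategies and CGH, with SNP genotyping
used to confirm already-retained variants.

* **Mendelian**: a region validates when some pedigree record has the
  offspring and at least one listed parent among the carriers.  The
  reported Mendelian percentage uses as denominator the regions carried
  by *any* pedigree member — the population of variants observable in
  trios/pairs at all.
* **Replicate (twice-sequenced)**: a region validates when, for some
  replicate animal carrying it, every one of that animal's runs
  contains a call of the matching type class with RO ≥ 0.70 to the
  region span.  Matching is against per-run *filtered raw calls* by
  default (recurrence "by at least one detection tool"); region-level
  matching is available by passing per-run consensus variants instead.
  Type classes: deletion-only regions match DEL calls, duplication-only
  match DUP, mixed CNVR regions match either.
* **External arrays**: RO ≥ 0.50 against the external call set, by
  default per animal (the external call must come from a carrier) and
  per type class.  Relaxed thresholds (0.20, 0.01) are just lower
  values of the same parameter; lowering the threshold is provably
  monotone in the validated count.

Rounding in reports is decimal half-up: validation rates to one
decimal, prose percentages to the nearest integer.

## Annotation and cohort statistics

Gene/QTL intersection classifies each overlap as partial,
feature-contained (an entire-gene deletion/duplication) or
region-contained.  Cohort tallies are exposed in both units — regions
hitting ≥ 1 gene, and distinct genes hit — because published gene
counts mix the two and the reader should not have to guess.  Breed
chi-square compares observed per-breed region counts with expectations
proportional to animals sequenced per breed
(`expected_b = total · n_b / N`); Pearson correlations use
`scipy.stats.pearsonr` and are reported as NaN for degenerate
(constant) inputs.  Chromosome coverage is the union of region spans,
never the sum, so covered bp can never exceed chromosome length.

## The simulator

The generator emulates the study design the pipeline targets, not
sequence data.  `SimConfig.study()` is the full design: 200 animals in
8 breeds (25 Blonde d'Aquitaine, 3 Brown Swiss, 25 Charolaise, 56
Holstein, 34 Limousine, 31 Montbéliarde, 23 Normande, 3 Rouge des Prés),
per-breed coverage ranges within 8–33×, two trios, 16 sire–son pairs
and 14 twice-sequenced animals, on a 29-autosome genome scaled to
100 Mb by default (locus counts scale with genome size to keep density
realistic; the full 2.5-Gb autosomal genome is ~25× larger).
`SimConfig.demo()` is a 20-animal, 2×5-Mb miniature used in tests and
examples.

* **Truth loci** are placed non-overlapping, clear of gaps by a 150-bp
  margin (so the gap filters cannot clip true events and adjacent loci
  cannot merge spuriously).  Sizes are log-normal: deletions
  median 1.5 kb with σ = 1.17 (upper quartile ≈ 3.3 kb), duplications
  median 8.7 kb with σ = 1.01 (lower quartile ≈ 4.4 kb).  The
  parametric family is an assumption; only the quartiles are
  calibrated.  Each locus size is drawn once and kept through placement
  retries — re-drawing on rejection measurably biases accepted sizes
  small; a stuck locus re-draws only after 100 failed positions.
* **Population structure**: each locus gets an allele frequency from a
  rare/common mixture (50% uniform 0.5–5%, 50% uniform 10–97%) to
  exercise the carrier-frequency spectrum from single-carrier to
  near-fixed regions.  Founders carry loci by Bernoulli draws; pedigree
  offspring carry exactly the loci inherited from carrier parents, each
  with the transmission probability (default 0.5, the Mendelian
  expectation for a heterozygous parent).  No de-novo events in
  offspring: this idealisation makes the Mendelian validation rate
  analytically predictable, which is what the recovery tests check.
* **Callers** are phenomenological profiles: detection is Bernoulli per
  locus with the tool's sensitivity; breakpoints get independent
  Gaussian jitter; RD-style tools snap breakpoints outward to a 250-bp
  window grid and report no supporting-read count; support for the
  others is Poisson with mean `intercept + slope · coverage`; false
  positives are Poisson per Mb with random type and sizes from the type
  distribution.  Default sensitivities/false-positive rates (cnvnator
  0.80/0.10, breakdancer 0.85/0.20, pindel 0.70/0.05, delly 0.85/0.15
  per Mb) are stylised to reproduce the qualitative tool behaviour the
  design assumes: PEM generous and noisy, SR precise, RD
  window-limited.  False positives are independent across tools — no
  correlated-artifact model.  Replicate runs redraw all noise
  independently from the same truth.

What passing tests on this generator do **not** show: real callers have
correlated errors (shared alignment artifacts), coverage-dependent
sensitivity, and breakpoint biases far from Gaussian; the simulator's
noiseless and analytic limits validate the pipeline's logic, not any
claim about real-data accuracy.

## Numerical and degenerate-input choices

* Pearson correlation on fewer than two points or constant input → NaN.
* Validation rate with zero predicted → NaN (printed "NA" in reports).
* Empty gap track: gap rules remove nothing.  Empty region list: writers
  emit header-only files.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng([seed, stage])`; identical configs produce
  byte-identical fixture bundles and reports.
* Determinism of outputs is by sorting, never by dict order: calls by
  (chrom, start, end, tool, sample, run), regions by (chrom, start).

## Problem sizes

Tests and the acceptance script use the demo scale (20 animals, 200
loci, 10 Mb) for end-to-end runs, 1000-locus single-carrier cohorts on
120 Mb for the binomial/Mendelian recovery checks, and the 100-Mb study
preset for cohort-level smoke runs; these sizes give 3-binomial-SE
resolution on the recovered fractions while keeping any single run in
seconds.

## Known limitations

* Region numbering, and therefore any specific published CNVR id, is
  not reconstructable from data.
* The ≥ 2-tool rule combined with one RD tool biases against large
  duplications (only one tool sees them well) — a property of the
  design itself, visible in the simulated duplication counts.
* Single-linkage chaining can produce very large regions; no chain
  breaking is attempted.
* No copy-number genotyping, breakpoint refinement, GO/pathway
  enrichment or external-database comparison beyond generic external
  call sets in the canonical TSV dialect.
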
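# cnvcons

Multi-caller copy-number-variant (CNV) consensus calling, CNV-region
(CNVR) construction, validation and annotation for cohort sequencing
studies — with a synthetic caller-output generator so the whole workflow
runs and can be scored at desk scale without any sequencing data.

## The problem

Individual structural-variant callers disagree wildly: read-depth (RD)
tools see large events at window resolution, paired-end-mapping (PEM)
tools discover aggressively but with many false positives, and
split-read (SR) tools are precise but less sensitive.  A standard remedy
in population CNV surveys is a consensus-and-merge design:

1. **Filter** each tool's per-sample calls — drop calls whose
   breakpoints sit within 100 bp of an assembly gap, calls that are more
   than 25% gap ('N') sequence, calls with fewer than 3 supporting
   reads, and calls below the 50-bp CNV size floor.
2. **Consensus within a sample** — keep a variant only if at least two
   different tools predicted it.  Two calls are "the same variant" when
   they share ≥ 90% reciprocal overlap,
   `RO(a,b) = min(|a∩b|/|a|, |a∩b|/|b|)`; for the split-read pair
   (pindel + delly) the criterion is instead agreement of both
   breakpoints within 100 bp.  Matching calls form connected components;
   each component with ≥ 2 distinct tools becomes one consensus variant
   spanning its members.
3. **Merge across samples** — consensus variants from different animals
   cluster by single linkage at ≥ 70% RO; each cluster becomes a region
   spanning its lowest 5′ to highest 3′ position, typed *deletion-only*,
   *duplication-only*, or *CNVR* when both types contributed.
4. **Validate** — a region is retained when it passes Mendelian
   transmission (carried by an offspring and one of its sequenced
   parents), recurs in every independent sequencing run of a
   twice-sequenced animal (RO ≥ 70%), or is matched by an array-CGH call
   (RO ≥ 50%, same animal and type); SNP-array support is recorded as an
   extra confirmation.
5. **Annotate** — validated regions are intersected with gene and QTL
   intervals (partial / entire-gene / region-inside-feature classes) and
   summarised by carrier frequency, breed sharing, chromosome coverage,
   Pearson correlations (count vs chromosome length, count vs coverage)
   and a chi-square test of per-breed counts against the number of
   animals sequenced per breed.

`cnvcons` implements this workflow as a typed Python library plus a thin
CLI, and ships a simulator that emulates the study design it was built
for: a 200-animal, 8-breed cattle cohort at 8–33× coverage with two
sire–dam–son trios, 16 sire–son pairs and 14 twice-sequenced animals,
called by four tools (RD / PEM / 2×SR) with per-tool sensitivity,
breakpoint jitter, window-grid snapping and false-positive rates.

## Worked example

```python
from cnvcons import (SimConfig, simulate_truth, emulate_callers, run_pipeline)

config = SimConfig.demo(seed=42)            # 2 chromosomes × 5 Mb, 20 animals
truth = simulate_truth(config)              # genome, cohort, true CNV loci
calls = emulate_callers(truth)              # noisy per-tool call sets
result = run_pipeline(
    calls, truth.gaps, truth.samples, truth.chrom_lengths,
    pedigree=truth.pedigree, genes=truth.genes, qtl=truth.qtl,
)
```

prints (via the report fields on `result`):

```
raw calls:            3373
after filters:        3298
consensus variants:   778
regions:              123
validated regions:    72
replicate concordance: 1.00
Mendelian validated:  60%
           combination  n_predicted  n_validated  validation_rate_pct
breakdancer + cnvnator           60           42                 70.0
   breakdancer + delly           97           66                 68.0
  breakdancer + pindel           90           61                 67.8
      cnvnator + delly           52           36                 69.2
     cnvnator + pindel           50           36                 72.0
        delly + pindel          113           72                 63.7
                 Total          123           72                 58.5
```

Reading this: 3373 raw calls survive the gap/support/size filters almost
intact (the demo genome has few gaps), collapse to 778 within-sample
consensus variants (the ≥ 2-tool rule discards most single-tool calls),
and merge into 123 cross-sample regions, of which 72 are validated by
Mendelian transmission, replicate recurrence, or both.  The
per-combination table counts each region once per pair of tools that
matched inside it, so rows sum to more than the total.

The same run is available from the shell:

```bash
cnvcons simulate --preset demo --seed 42 --out fixtures/
cnvcons run-all config.yaml          # see `cnvcons run-all --help` for the schema
```

## Layout

- `src/cnvcons/core.py` — domain types and interval algebra (reciprocal
  overlap, breakpoint matching, gap arithmetic)
- `src/cnvcons/io.py` — canonical TSV/BED/GFF3/VCF readers and writers,
  native-caller adapters
- `src/cnvcons/filtering.py` — pre-consensus filters with removal accounting
- `src/cnvcons/consensus.py` — within-sample ≥ 2-tool consensus
- `src/cnvcons/regions.py` — cross-sample merging and cohort summaries
- `src/cnvcons/validation.py` — Mendelian / replicate / external-array validation
- `src/cnvcons/annotation.py` — gene/QTL intersection and frequency reports
- `src/cnvcons/simulate.py` — cohort, truth and caller-output simulator
- `src/cnvcons/pipeline.py`, `src/cnvcons/cli.py` — orchestration and CLI

See `docs/methods.md` for the model, parameter defaults, numerical
conventions and known limitations.
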
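# bsmethyl

A bacterial bisulfite (m5C) methylome toolkit built around a fully
synthetic, ground-truth-bearing test bed. It covers the complete analysis
chain for a GC-rich linear chromosome:

- **`bsmethyl.synthdata`** — generate a random GC-rich genome, a
  non-overlapping gene annotation, a planted methylome (anchored motifs
  such as `GGCmCGG` = `GGCCGG`/anchor 4 written into gene upstream regions,
  plus per-context background methylation), and directional
  bisulfite-converted reads (OT/OB) with configurable conversion
  efficiency, sequencing error and coverage — with a truth table for every
  planted site.
- **`bsmethyl.bsmap`** — reduced-alphabet (C→T / G→A) k-mer-seeded ungapped
  bisulfite alignment with bisulfite-aware mismatch scoring and strict
  ambiguity handling.
- **`bsmethyl.mcall`** — per-cytosine pileup, CG/CHG/CHH context
  classification (H = A, T or C), and methylation calling by exact binomial
  test against the non-conversion rate with Benjamini–Hochberg correction.
- **`bsmethyl.landscape`** — fixed-width window profiles along the
  chromosome (default 250 kbp), two-sample window deltas, and per-site
  BED/bedGraph tracks with figures.
- **`bsmethyl.regions`** — strand-aware upstream regions (−500/+100 bp
  around each translation start), per-gene methylated-site reports, and
  anchored consensus-motif discovery by exact-k-mer enrichment against the
  genome-wide anchored background.
- **`bsmethyl.cli`** — `bsmethyl` command with `simulate`, `map`, `call`,
  `landscape`, `regions` and `run-all` subcommands.

Coordinates are 0-based half-open internally; GFF3, SAM and the cytosine
report use their native 1-based conventions.

## Quick start

One-command synthetic demonstration (simulate → map → call → landscape →
regions, with a manifest and a truth-recovery summary):

```bash
bsmethyl run-all --outdir demo --seed 7
cat demo/summary.json
```

Stage by stage:

```bash
bsmethyl simulate --outdir sim --seed 7            # genome.fa genes.gff3 truth.tsv reads.fastq
bsmethyl map --genome sim/genome.fa --reads sim/reads.fastq --out sim/aln.sam -k 16
bsmethyl call --genome sim/genome.fa --aln sim/aln.sam --epsilon 0.005 --out sim/calls.tsv
bsmethyl landscape --calls sim/calls.tsv --genome sim/genome.fa --window 250000 --out sim/landscape
bsmethyl regions --calls sim/calls.tsv --gff sim/genes.gff3 --genome sim/genome.fa --out sim/regions
```

All parameters can be supplied as a JSON config (`--config cfg.json`);
unknown keys are rejected. See `bsmethyl.pipeline.PipelineConfig` for the
full set and defaults.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the full-scale acceptance battery
(1 Mbp end-to-end recovery, motif and gene-set recovery, caller
calibration over five seeds, and exhaustive oracle-equivalence checks for
the mapper, the context classifier, the binomial tail, window binning and
region arithmetic). The whole suite runs in a few minutes on one CPU.

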
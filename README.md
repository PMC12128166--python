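# methylink

Toolkit for linking SMRT-detected DNA base modifications to gene expression
in bacterial genomes. It covers the full analysis chain:

- **io_formats** — FASTA genomes, ipdSummary-style base-modification GFF3
  (kinModCall dialect), CDS annotation GFF3, BED island intervals, and TSV
  result tables (all coordinates normalised to 1-based inclusive).
- **expression** — RPKM / TPM from raw counts, equal-size expression
  categories, and per-gene category shifts between two conditions.
- **motifs** — IUPAC motif scanning on both strands of circular genomes
  (motifs written with lowercase methylated letters, e.g. `AgGCcT`,
  `GaTNNNNNGtGG`), canonical / non-canonical call classification, and
  fully / partially / unmethylated site accounting (score cutoff 21).
- **landscape** — sliding-window GC content / GC skew / modification
  density profiles, Spearman correlation with percentile-bootstrap
  confidence intervals, and region-bias Z statistics
  `Z = (F_obs − F_exp) / sqrt(F_exp + 1)` over coding / noncoding /
  TSC-upstream and island / core genome partitions.
- **association** — the core inference: TSC-relative sliding-window 2×2
  contingency analysis (`[[a,b],[c,d]]`: modification change × expression
  change), chi-squared p-values, raw LD and margin-normalised LD′,
  Benjamini-Hochberg FDR control, an exact binomial robustness test, and
  a parameter-grid sweep producing a per-offset significant-window profile.
- **synth** — synthetic genomes, planted motifs, two-condition methylomes
  and expression tables with tunable coupling between TSC-proximal
  modification changes and expression shifts, plus ground truth for
  every planted effect.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion. The
real-chromosome motif census is skipped unless a local copy of the
NC_008260 FASTA is supplied via the `METHYLINK_NC008260` environment
variable (it cannot be fetched offline).

## CLI

Each analysis stage is a subcommand (run `methylink COMMAND --help`):

```sh
# synthetic input bundle with a planted coupling at -80..-20 bp
methylink synthesize --out demo --seed 1 --coupling-strength 0.9

# per-condition expression table
methylink expression --counts demo/counts_A.tsv \
    --annotation demo/annotation.gff3 --out expr_A.tsv -k 3

# motif census + canonical/non-canonical split
methylink motifs --genome demo/genome.fasta \
    --mods demo/modifications_A.gff3 --out motifs_out

# chromosome landscape statistics
methylink landscape --genome demo/genome.fasta \
    --mods demo/modifications_A.gff3 \
    --annotation demo/annotation.gff3 --out landscape_out

# TSC-relative association sweep (presets: wide = windows 27..87 bp,
# k 3..6, cutoffs 100..200; narrow = windows 20..50 bp, k 4..8,
# cutoffs 20..50)
methylink associate --genome demo/genome.fasta \
    --annotation demo/annotation.gff3 \
    --mods-a demo/modifications_A.gff3 --mods-b demo/modifications_B.gff3 \
    --counts-a demo/counts_A.tsv --counts-b demo/counts_B.tsv \
    --out assoc_out --preset wide

# everything from one JSON config
methylink run-all --config pipeline.json
```

All subcommands accept `--dry-run` (validate and print the plan without
writing) and stage outputs include a `manifest.json` with the config echo
and input checksums.

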
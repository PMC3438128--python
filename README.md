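# cisenrich

Randomization-based enrichment analysis of cis-regulatory elements in
promoter sets.

Given a genomic pool of promoter sequences (e.g. a TAIR-style
`upstream_1000` FASTA, one −1000..−1 record per gene) and a list of genes
of interest (say, all genes induced by a hormone treatment), `cisenrich`
asks: which transcription-factor binding sites — and which ordered
combinations of them — occur in the promoters of those genes more (or
less) often than chance? It is aimed at plant regulatory genomics, where
degenerate consensus sites such as auxin response elements (TGTCTC /
TGTCYS), G-box related elements (BACGTV) and MYB/MYC sites are routinely
screened in upstream regions, but nothing in it is plant-specific.

## Method

Motifs are IUPAC-degenerate words matched on both strands
("auto-antisense": a word and its reverse complement, with a
dyad-symmetric span counted once). A *module* is an ordered pair or
triple of motifs forming one composite unit: member hits must be
non-overlapping, in 5'→3' order, with a flexible gap of at most 100 bp
between consecutive members; orientation matters (GRE–AUX2 ≠ AUX2–GRE).

For an experimental set of *n* promoters, four statistics are computed
per target: **I** the number of promoters containing it, **II** the mean
occurrences per promoter (motif density), **III** the total occurrence
count, and **IV** the variance of per-promoter counts. The background is
*real randomization*: ≥1000 random sets of the same size *n* drawn
without replacement from the genomic pool, all targets sharing the same
draws. Significance is a standard Z-score against the empirical
background,

    z = (observed − mean_background) / sd_background,

with a one-sided normal tail p-value in the observed direction
(enrichment or depletion) and Bonferroni correction over the family of
targets × parameters (retain corrected p ≤ 0.05; for uncorrected
p-values use α ≤ 0.01). The Z-test presumes an approximately Gaussian
background, so every call carries a moment-based normality flag; for
extremely overabundant motifs parameter I breaks this assumption and
parameter II is consulted instead. A built-in false-positive-rate
procedure re-runs the whole pipeline on random "experimental" sets to
verify calibration empirically.

## Worked example

The 62-nt synthetic AtGH3.3-derived "GRAUX" promoter fragment carries
one G-box related element and two auxin response elements:

```python
>>> from cisenrich import GRAUX_OLIGO, default_registry, scan_motif, scan_module
>>> from cisenrich.scanner import ModuleSpec
>>> reg = default_registry()
>>> [(h.start, h.end, h.strand) for h in scan_motif(GRAUX_OLIGO, reg["GRE"])]
[(20, 26, 'watson')]
>>> [(h.start, h.end) for h in scan_motif(GRAUX_OLIGO, reg["AUX2"])]
[(39, 45), (46, 52)]
>>> len(scan_module(GRAUX_OLIGO, ModuleSpec.from_members(["GRE", "AUX2"]), reg))
2
>>> len(scan_module(GRAUX_OLIGO, ModuleSpec.from_members(["AUX2", "GRE"]), reg))
0
```

The single GRE (the TACGTG span at 20–26) pairs with each downstream
AUX2 hit within the 100-bp window, giving two GRE→AUX2 module instances
and none in the opposite orientation.

A full analysis from the shell, on a simulated genome-scale pool with a
planted signal:

```sh
cisenrich simulate --pool-size 30000 --exp-size 200 \
    --plant RY:0.05:0.5 --seed 1 --out-dir scenario
cisenrich enrich --pool scenario/pool.fa --genes scenario/experimental.txt \
    --reps 1000 --seed 7 --out-dir results
```

which reports, e.g.

```
experimental: n=200 promoters vs pool of 30000; 8 significant target x parameter calls -> results
```

`results/records.tsv` holds one row per target × parameter (observed
value, background mean/SD, z, raw and corrected p, direction, normality
flag), `results/occurrence.tsv` the ranked list of significantly
enriched targets present in ≥5% of the analysed promoters (an asterisk
marks density-only calls), and `results/matrix.tsv` the coded
significance matrix.

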
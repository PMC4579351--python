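# exoarch

Promoter-architecture analysis for strand-specific exonuclease stop-site
(ChIP-exo) data, built around a coregulated yeast gene cohort: peak-pair
calling, motif maps, factor occupancy tables, binding-breadth classes,
anchored composite profiles, and +1-nucleosome shift estimation — plus a
synthetic ChIP-exo/MNase data generator with retained ground truth so
every stage is testable without sequencing data.

## Modules

| module | what it does |
| --- | --- |
| `exoarch.synthetic_data` | synthetic genome, promoter layouts, ChIP-exo tag and MNase fragment simulation under three conditions (normal, heat shock, hmo1-null) |
| `exoarch.tagio` | BED/bedGraph I/O, strand-aware 3' tag shifting, per-base pileups |
| `exoarch.peakcall` | Gaussian-smoothed greedy peak calling (sigma 5, exclusion 20), opposite-strand peak pairing (≤100 bp), pair filtering, cross-condition background normalization |
| `exoarch.motifscan` | IUPAC consensus scanning, PWM scanning with exact DP p-values, poly(dA:dT) tracts, peak-proximal retention (±40 bp), TSS assignment (<500 bp) |
| `exoarch.occupancy` | windowed occupancy sums, log2-median + percent-rank normalization, binding-breadth measurement/classification, heat-shock fold changes, ectopic PIC fractions, factor correlation matrix |
| `exoarch.composite` | anchor-aligned orientation-corrected composites, per-gene heat-map matrices, strand-specific pattern similarity (piggyback detection) |
| `exoarch.nucpos` | dyad densities from MNase fragments or histone ChIP-exo, +1-nucleosome calling, dyad-shift estimation, TSS burial geometry |
| `exoarch.pipeline_cli` | config-driven end-to-end orchestration (`exoarch` CLI) |

## CLI

```sh
# write a synthetic dataset bundle (genome.fa, annotation.tsv, per-factor
# tag BEDs, MNase fragment BEDs, truth.json, manifest.json)
exoarch simulate --out simdata --seed 1

# run the full analysis chain on it (peaks, pairs, motif sites,
# occupancy tables, breadth classes, composites, dyad shifts, report)
exoarch analyze simdata --out results

exoarch report results
```

Parameters can be overridden with a YAML config (`--config cfg.yaml`,
top-level `simulate:` / `analyze:` sections); exit codes are 0 (ok),
2 (config error), 3 (data error).

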
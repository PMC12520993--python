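# pegsensor

Design of prime editing **sensor** libraries and deconvolution of the
pooled screens they enable.

Prime editing installs arbitrary small edits (SNVs, insertions, deletions)
from a pegRNA that carries both a *search* sequence (the protospacer) and a
*replace* sequence (the 3′ extension: reverse-transcription template, RTT,
followed by the primer binding site, PBS). Screening variant libraries with
prime editing is confounded by the enormous variability in editing
efficiency between pegRNAs: an inert pegRNA and a neutral variant look
identical in an enrichment screen. The sensor strategy resolves this by
placing a 60-nt synthetic copy of each pegRNA's endogenous target site on
the same cassette, so sequencing the construct reads out, per pegRNA, both
its abundance (fitness proxy) and its empirical editing activity at the
sensor — which can then be used to filter ("calibrate") the enrichment
statistics to pegRNAs that demonstrably edit.

`pegsensor` implements the full desk-side stack for this design:

- **variant_io** — gene models (FASTA + CDS intervals), MAF-like variant
  tables (1-based in, 0-based internally), translated consequence classes,
  and evenly tiled synonymous (silent) control variants.
- **design / pipeline** — NGG protospacer enumeration on both strands,
  pegRNA construction over the RTT × PBS grid (10/15/20/25/30 × 10/13/15 nt),
  features (distance to nick, post-edit homology, PBS/RTT GC, PAM and
  protospacer disruption), cloning filters (U6 polyT terminator, EcoRI,
  Esp3I, MIT specificity < 50), a linear composite score, and per-variant
  ranking capped at 30 designs.
- **specificity** — brute-force Hsu position-weight off-target scoring
  against a user-supplied surrogate genome,
  `score = 100·100 / (100 + Σ site penalties)`.
- **sensor** — the 60-nt sensor (24 nt upstream / 36 nt downstream of the
  nick on the PAM strand, stored in reverse orientation), 5-nt terminal
  barcodes, barcode-collision flagging, full-oligo assembly with the
  cloning adapters, and manifest/FASTA export.
- **deconvolution** — FASTQ streams (separate spacer / extension / sensor
  reads per cluster), mean-Phred ≥ 30 filter, exact spacer+extension
  matching with recombination and unmatched calls, barcode-checked sensor
  outcome classification (CORRECT / UNEDITED / INDEL / OTHER) inside a
  quantification window that excludes both barcodes, and plasmid-background
  subtraction.
- **screen_stats** — median-of-ratios normalization, `log2` fold change of
  replicate medians with pseudocount 1, control-count filter (mean ≥ 10),
  population Z-scores, a two-sided empirical FDR built from the silent
  controls (Benjamini–Hochberg), sensor calibration with threshold sweeps,
  best-pegRNA-per-variant aggregation, feature correlations and ΔZ
  comparison against external (e.g. cDNA overexpression) Z-score tables.
- **simdata** — fully synthetic gene models, variant sets and screens with
  known per-design editing rates, per-variant fitness effects (acting only
  on the edited subpopulation), recombination and quality contamination —
  so every stage is testable without any downloads.

## Worked example

```python
from pegsensor import simdata, screen_stats as ss
from pegsensor.pipeline import DesignParams, design_library
from pegsensor.sensor import export_library
from pegsensor.variant_io import (
    dedupe_variants, generate_silent_controls, parse_variant_table,
)

gene = simdata.simulate_gene(seed=1, length=1200)
table = simdata.simulate_variant_table(gene, n_snv=12, n_ins=2, n_del=2, seed=1)
variants, rejects = parse_variant_table(table, gene)
variants = dedupe_variants(variants + generate_silent_controls(gene, 40))
designs, report = design_library(gene, variants, DesignParams(max_per_variant=3))
manifest = export_library(designs, variant_classes={v.id: v.vclass for v in variants})
print(len(variants), len(manifest))   # 56 variants, 156 designs

truth = simdata.SimTruth.generate(manifest, seed=2, depth=300)
counts, summaries, dtruth = simdata.simulate_counts(manifest, truth)
lfc = ss.compute_lfc(counts, ["ctrl_r1", "ctrl_r2", "ctrl_r3"],
                     ["trt_r1", "trt_r2", "trt_r3"])
editing = ss.summarize_editing(summaries, ["trt_r1", "trt_r2", "trt_r3"])
silent = manifest.loc[manifest.vclass == "silent", "design_id"]
cal = ss.sensor_calibrate(lfc, editing, silent, min_correct_pct=10.0,
                          min_sensor_reads=10)
print(int(cal.passed_calibration.sum()))  # 84 of 156 designs calibrated
print(cal[cal.passed_calibration].nlargest(3, "zscore")
        [["lfc", "zscore", "fdr", "sensor_correct_pct"]].round(3))
```

prints

```
                         lfc  zscore    fdr  sensor_correct_pct
design_id
simgene1_328A>T_pe03   3.532   5.477  0.174              23.077
simgene1_328A>T_pe01   3.377   5.230  0.174              20.279
simgene1_1094G>C_pe02  2.279   3.486  0.174              70.172
```

Two independent designs of the same simulated variant (328A>T, whose true
fitness effect is +0.56 log2/passage) top the calibrated Z-scores — the
behavior the sensor filter exists to produce. At this miniature scale (40
silent controls) the empirical FDR is deliberately conservative; the test
suite exercises the statistics at realistic silent-control counts.

The same flow is available from the shell via `pegsensor design`,
`pegsensor simulate`, `pegsensor deconvolve` and `pegsensor analyze`
(see `pegsensor --help`).

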
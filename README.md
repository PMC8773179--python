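# gsis-screen

Analysis toolkit for arrayed siRNA screens with a glucose-stimulated insulin
secretion (GSIS) readout in 384-well format:

- **`library_layout`** — load a siRNA library table, build randomized
  triplicate plate layouts with reserved non-targeting (NT) and control-gene
  wells, validate them, and emit acoustic-dispenser (ECHO-style) picklists
  sorted so each source plate is picked in one contiguous block.
- **`synthetic_screen`** — a generative model of the screen (multiplicative
  condition folds, planted gene effects, per-plate scale factors, log-normal
  well noise, truncated-Gaussian cell counts) plus a synthetic library and a
  qPCR Ct-table generator, so the whole pipeline runs without external data.
- **`ssmd_hit_calling`** — strictly standardized mean difference (SSMD)
  scoring of every gene against the on-plate NT wells for both secretion and
  cell number, inclusive ±1.5 hit cut-offs, a cell-number viability filter
  for down-hits, Venn-style integration across conditions, control QC and NT
  fold-induction checks.
- **`qpcr_ddct`** — comparative Ct (ddCt) relative expression and knockdown
  summaries.
- **`pipeline` / `cli`** — one reproducible run
  (design → simulate → score → report) with per-stage derived seeds and a
  manifest of content digests.

The default configuration mirrors the screen geometry this package targets:
521 candidate genes in triplicate at 75 genes per plate → 7 plate sets, each
replicated across three conditions (0 mM glucose, 20 mM glucose,
20 mM glucose + IBMX) → 21 assay plates, with 33 NT wells and 8 wells for
each of the INSULIN/PLK1/ZMIZ1/HNF4A control siRNAs per plate.

## CLI

```bash
# full pipeline into ./out (synthetic library by default)
gsis-screen run --seed 42 --out out/

# stages individually (any stage re-runs from prior outputs in --out)
gsis-screen design --library lib.csv --replicates 3 --capacity 75 \
    --conditions 0mM,20mM,20mM+IBMX --seed 42 --out out/
gsis-screen simulate --seed 42 --out out/
gsis-screen score --up-cut 1.5 --down-cut -1.5 --viability-cut -1.5 --out out/
gsis-screen report --out out/

# ddCt quantification from a Ct table
gsis-screen qpcr --ct ct.csv --calibrator NT --out out/
```

Every default is overridable from a YAML/JSON config passed with `--config`;
the effective config, stage seeds and output digests are recorded in
`manifest.json`. Outputs are plain CSV/JSON plus a markdown summary.

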
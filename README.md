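# cmapneuro

A toolkit for targeted, bead-based chemical-genetic screening of the
Connectivity-Map kind, built around a neuronal probe panel in which each
Luminex bead color reports exactly one gene (no peak deconvolution).  It
covers the complete path from raw bead fluorescence to queryable
perturbational signatures:

1. **Signal pipeline (Levels 1–5).**  Raw bead fluorescence intensities
   (Level 1) are median-collapsed per analyte and well into MFI values
   (Level 2); each well is loess-normalized against ten invariant gene
   sets with level-ordered reference expression and all wells on a plate
   are quantile-normalized to a shared empirical distribution (Level 3);
   gene-wise robust z-scores are computed against the plate population,
   z = (x − median) / (1.4826 · MAD) (Level 4); biological replicates are
   collapsed by a weighted average, each replicate weighted by its mean
   Spearman correlation to the others (Level 5).
2. **Signature quality metrics.**  Replicate correlation
   CC = Q75 of pairwise Spearman correlations across Level 4 replicates;
   signature strength SS = #{genes : |z·√N| > 2}; transcriptional
   activity score TAS = √(SS · max(CC, 0) / G) with G = 467 for the full
   neuro panel.
3. **Probe-panel validation.**  Gene recall against a reference
   expression matrix: the percentage of reference-transcriptome genes
   whose profile correlates better with a probe's measurements than the
   probe's own gene (rank ≤ 5 % good, ≤ 10 % moderate, else poor), plus
   low-expression stratification and cross-dataset signature recall with
   a TAS ≥ 0.212 activity filter.
4. **Connectivity queries.**  Up/down gene-set queries against the
   signature corpus via the weighted Kolmogorov–Smirnov enrichment score,
   WTCS = (ES_up − ES_down)/2 for opposite-sign pairs, normalized within
   cell-line × perturbagen-type strata (NCS) and converted to a signed
   percentile τ ∈ [−100, 100]; perturbagens are ranked by median τ and
   labeled *mimic* (positive) or *reverse* (negative).
5. **Synthetic screens.**  A seeded generator for bead-level data with
   384-well plate structure, invariant-gene behavior, well gains, plate
   shifts and planted compound effects with known ground truth, so every
   stage above is testable without external data.

## Worked example

Simulate a one-plate screen, process it to Level 5, score signatures and
run a self-query:

```bash
cmapneuro simulate --config sim.yaml --out-dir sim     # beads.csv, meta.csv, panel.tsv, truth.json
cmapneuro process --beads sim/beads.csv --meta sim/meta.csv \
    --panel sim/panel.tsv --out-dir proc               # level2.gct ... level5.gct, report.json
cmapneuro tas --level4 proc/level4.gct --level5 proc/level5.gct --out metrics.csv
cmapneuro query --up up.gmt --down dn.gmt --corpus proc/level5.gct --out q.csv
```

With `sim.yaml` holding `{seed: 5, n_compounds: 4, doses: [5.0],
n_replicates: 3, n_vehicle_wells: 8, beads_per_analyte: 5}`, the metrics
table starts

```
signature_id,cell_line,pert_id,dose,time,n,cc,ss,tas
CPD000|5.0|24.0|NGN2_line1,NGN2_line1,CPD000,5.0,24.0,3,0.1370,52,0.1235
CPD001|5.0|24.0|NGN2_line1,NGN2_line1,CPD001,5.0,24.0,3,0.1962,59,0.1574
```

— each row is one replicate-collapsed signature with its replicate count
n, reproducibility CC, strength SS (genes moved beyond the z = 2 band
after √n adjustment) and combined activity TAS.  Querying the corpus
with the top/bottom 10 genes of CPD000's own signature returns

```
signature_id,pert_id,...,wtcs,ncs,tau,median_tau,label
CPD000|...,CPD000,...,1.000, 1.000, 40.0, 40.0,mimic
CPD001|...,CPD001,...,-0.763,-1.148,-80.0,-80.0,reverse
```

so the query's source compound scores WTCS ≈ 1 (its up genes sit at the
very top of its own ranking, its down genes at the very bottom) and is
labeled a mimic, while anti-correlated compounds come back as reversers.

The same functionality is available as a library
(`cmapneuro.run_pipeline`, `cmapneuro.annotate_signatures`,
`cmapneuro.query`, ...); see the module docstrings.

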
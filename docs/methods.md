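# Methods

## Assay model

The package models a targeted Luminex expression assay: mRNA from
compound- or vehicle-treated wells of a 384-well plate (rows A–P,
columns 1–24) is amplified with gene-specific barcoded probes,
hybridized to color-coded beads and read as per-bead fluorescence
intensities (FI).  The panel couples **one gene to each bead color**, so
the dual-gene peak-deconvolution step of the classical 978-gene design
has no counterpart here; the median over a barcode's beads is directly
the gene's measurement.  The measured panel (G = 467 genes by default;
any size in simulation) is accompanied by **ten invariant gene sets** —
groups of genes with stable expression at ten strictly increasing
reference levels — carried on their own barcodes and used only for
normalization.

## Processing levels

**Level 2 (MFI).**  Median FI across a barcode's beads per well.
Analytes with zero beads become missing values (never 0 — zero is a
legal intensity); wells missing more than a configurable fraction
(default 50 %) of analytes are flagged failed.

**Level 3 (normalization).**  Per well, the ten (invariant-set median
MFI → reference level) pairs anchor a degree-1 tricube-weighted loess
map that is applied to every gene's MFI.  The fit is done on the
log2(x+1) scale: the anchors are near-equispaced and near-colinear
there, which keeps the wide-span fit accurate at low intensities,
whereas a raw-scale fit over log-spaced anchors degenerates toward a
single global line dominated by the bright anchors.  Span is 1.0 (ten
points cannot support a narrow window) and queries beyond the anchor
range extend the boundary fit linearly.  Wells with fewer than ten
usable anchors are excluded and logged.  All wells on a plate are then
quantile-normalized: each well's k-th order statistic is replaced by the
plate-mean k-th order statistic, so every well on a plate shares one
empirical distribution; exact ties receive the mean of their tied order
statistics.  The target vector is averaged in a fixed (sorted) summand
order so the pipeline is exactly invariant to sample ordering.  Output
stays on the log2 scale by default (`log_transform=True`); invariant
rows are dropped after use.

**Level 4 (robust z).**  Per gene and plate, with the reference
population being *all* samples on the plate (vehicle wells included):

    z = (x − median) / (1.4826 · max(MAD, 0.01))

The 1.4826 factor makes MAD consistent with a normal σ; the 0.01 floor
(log2 scale) keeps constant genes finite (their z becomes 0, logged).
Plates need at least 4 samples.

**Level 5 (replicate collapse).**  Replicates of one condition are
combined as Σ wᵢ zᵢ where each raw weight is the replicate's mean
Spearman correlation to the others, floored at 0.01 (anti-correlated
replicates would otherwise get negative weight) and normalized to sum 1.
Singleton groups pass through with weight 1.  Weights are therefore
nonnegative and each collapsed value lies inside the replicates'
elementwise envelope.

## Signature metrics

* **CC** — 75th percentile (linear interpolation between order
  statistics) of the pairwise Spearman correlations among a condition's
  Level 4 replicates.  Undefined (NaN) for single replicates; pairs with
  a constant vector are excluded with a warning.
* **SS** — count of genes with |z·√N| > 2 (strict inequality), N the
  replicate count.  The √N factor credits averaging: a reproducible
  moderate shift across many replicates is evidence of real activity.
  An unadjusted variant (`ss_variant="unadjusted"`) is kept for
  sensitivity checks.
* **TAS** — √(SS · max(CC, 0) / G).  Zero whenever the signature is
  irreproducible (CC ≤ 0, or CC undefined) or empty (SS = 0); 1 only
  when all G genes move strongly and replicates agree perfectly.  The
  geometric form keeps the score in [0, 1] and balances magnitude
  against reproducibility; the plain quotient is available as
  `tas_variant="literal"`.

## Probe and signature recall

Probe validation correlates each panel gene's baseline measurement
across cell lines (Spearman) with every row of a reference expression
matrix; the **recall rank** is the percentage of reference genes with
strictly higher correlation than the matched gene (ties do not count
against it).  Ranks ≤ 5 are *good*, ≤ 10 *moderate*, else *poor*; poor
probes are additionally stratified by mean reference expression, with
the low-expression cutoff defaulting to the lower tertile.  Signature
recall applies the same idea at the signature level between two
datasets sharing perturbagens: query signatures passing a TAS ≥ 0.212
activity filter are ranked against all reference signatures by Spearman
correlation, the matched perturbagen's best reference signature taking a
competition rank (1 + number of strictly better references).

## Connectivity

Queries are disjoint up/down gene-symbol sets (built from a DEG table by
taking the top n positive and top n negative log2 fold changes; both a
signed and an absolute-value sort key are exposed, and short sides are
truncated with a log message).  Against each signature, genes are ranked
by z descending and each set gets a weighted Kolmogorov–Smirnov
enrichment score: member genes step the running sum up by
|z| / Σ_members |z|, non-members down by 1/(N − |S|), ES = extremum of
largest magnitude.  WTCS = (ES_up − ES_down)/2 when the two scores have
opposite signs, else 0.  WTCS is normalized to NCS by dividing by the
mean |WTCS| of same-sign scores within the signature's cell-line ×
perturbagen-type stratum, and τ is the signed percentile of |NCS|
against the stratum's reference distribution (strictly-below counting,
ties excluded; sign(τ) = sign(NCS), τ = 0 for NCS = 0).  When no
precomputed reference distribution is attached to the corpus, the NCS
values of the current query within the stratum serve as the reference.
Per-perturbagen connectivity is the median τ over that perturbagen's
signatures; the top/bottom of the ranking are labeled mimic/reverse.
Query symbols absent from the panel are dropped with a logged count —
the unavoidable cost of querying a targeted panel with
transcriptome-wide DEG lists.  Touchstone (perturbagen–perturbagen)
similarity queries a perturbagen's own top/bottom 50 signature genes
against the rest of the corpus.

## Synthetic data

The generator emulates the screen's structure, not its biology.  Bead FI
for gene g in well w on plate p is

    FI = exp(baseline_g + δ_g·1[affected] + log g_w + shift_p + ε),
    ε ~ N(0, σ_bead²)

with per-well log-normal gains g_w (σ_well = 0.15), additive plate
shifts (σ_plate = 0.1), bead noise σ_bead = 0.1 and ~30 beads per
analyte.  Effects δ are additive on the natural-log scale (δ = ln 2 is a
2-fold change) and are planted on a random gene subset per active
compound; designated null compounds have δ = 0.  Invariant beads sit at
their set's reference level times g_w and never respond to compounds —
exactly the property the loess step relies on.  Vehicle wells occupy
fixed columns (23–24 by default, 24 wells/plate); treatments are
distributed round-robin across plates; defaults are 3 replicates per
condition and two doses (0.5 and 5 µM) at 24 h.  A paired
reference-expression generator produces (measured panel, large
reference) baseline matrices where each probe tracks its matched
reference row with a configurable fidelity in [0, 1] (1 = identical,
0 = independent); the reference defaults to 22,225 genes and is scaled
down in tests.  What the generator does **not** model: dose–response
shapes, kinetics, bead clumping or optical artifacts, correlated gene
programs, or any disease biology — so passing tests demonstrate the
correctness of the processing and query machinery, not performance on
real screens.

## Numerical choices and edge cases

* Quantile-normalization ties: mean of tied order statistics
  (deterministic).  Robust-z MAD floor 0.01; replicate-weight floor
  0.01; Spearman ties: average ranks.
* A planted shift that does not change a gene's within-well rank is
  erased exactly by quantile normalization (collapsed z = 0).  This can
  only happen at the distribution extremes — the affected value must
  stay above (or below) all its neighbors — and never produces a wrong
  sign; the noise-free recovery test therefore requires zero sign flips
  and ≥ 90 % effect survival rather than universal survival.
* Enrichment with an all-member set has no misses to step down and is
  defined as ES = 1; all-zero member weights fall back to the
  unweighted KS statistic.
* Recall-rank boundaries follow closed intervals (rank exactly 5 is
  *good*, exactly 10 *moderate*); fixtures avoid boundary values.
* GCT files are written as version 1.3 with sample metadata, processing
  level and provenance as column metadata (version 1.2 accepted on
  read); missing values are encoded `NA`, never 0.  Well ids normalize
  to zero-padded form (`A1` → `A01`).

## Problem sizes

Tests and the acceptance script run on scaled-down instances chosen to
exercise every code path with comfortable margins: 50-gene panels with
5-gene invariant sets, 1–4 plates, 40–80 signatures per corpus,
1,000-gene reference matrices, 100-repetition query studies.  These
sizes keep the full suite under a minute while leaving the statistical
checks (AUC ≥ 0.9, KS uniformity, self-query dominance ≥ 95 %) far from
their thresholds.

## Known limitations

No cross-plate batch correction beyond per-plate normalization; no
imputation beyond the measured panel; KD/OE consensus signatures are
treated as plain signatures (the perturbagen-type field is carried but
not specially modeled); GCTX/HDF5 binary matrices are not supported;
tau stratification by cell line × perturbagen type is one reasonable
convention among several for small corpora and is configurable via
explicit reference distributions.
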
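"""Level 1 → Level 5 signal processing.

The pipeline turns raw bead fluorescence into replicate-collapsed
perturbational signatures in four steps:

  Level 2  median-collapse bead FIs per analyte per well (MFI);
  Level 3  loess-normalize each well against the ten invariant gene sets
           (fit in log2 space), then quantile-normalize all wells on a
           plate to a common empirical distribution;
  Level 4  gene-wise robust z-scores against all samples on the plate,
           z = (x - median) / (1.4826 * max(MAD, floor));
  Level 5  collapse biological replicates with a weighted average, each
           replicate weighted by its mean Spearman correlation to the
           others.

The loess step uses a degree-1 tricube-weighted local fit over the ten
(invariant median MFI, reference level) anchors with span 1, extended
linearly beyond the anchor range.  With one gene per bead color there is
no peak-deconvolution step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import BeadTable, ExpressionMatrix, Level, ProbePanel, SampleMeta

logger = logging.getLogger("cmapneuro")


@dataclass
class PipelineConfig:
    loess_span: float = 1.0
    log_transform: bool = True  # keep Level 3+ on the log2(x+1) scale
    mad_scale: float = 1.4826
    mad_floor: float = 0.01
    min_weight: float = 0.01  # replicate-weight floor before normalization
    max_missing_fraction: float = 0.5  # sample failure threshold at Level 2
    quantile_tie_policy: str = "mean_of_order_stats"
    reference_scope: str = "plate"

    def __post_init__(self):
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess_span must be in (0, 1]")
        if self.mad_floor <= 0 or self.mad_scale <= 0 or self.min_weight <= 0:
            raise ValueError("scales and floors must be positive")
        if self.reference_scope != "plate":
            raise ValueError("only plate-scope reference populations are supported")


@dataclass
class ProcessingReport:
    """Side-channel diagnostics accumulated across the pipeline."""

    failed_samples: list[str] = field(default_factory=list)
    excluded_wells: list[str] = field(default_factory=list)
    missing_counts: dict[str, int] = field(default_factory=dict)
    floored_mad_genes: dict[str, int] = field(default_factory=dict)
    group_weights: dict[str, list[float]] = field(default_factory=dict)
    group_n: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Level 2: bead -> MFI
# ---------------------------------------------------------------------------

def level2_median_collapse(
    beads: BeadTable,
    panel: ProbePanel,
    samples: list[SampleMeta],
    cfg: PipelineConfig | None = None,
    report: ProcessingReport | None = None,
) -> ExpressionMatrix:
    """Median FI across beads per (sample, analyte).

    One gene per bead color, so the median over a barcode's beads is the
    gene's MFI directly.  Analytes with zero beads in a sample become
    missing values; samples exceeding the missing-fraction threshold are
    flagged failed (kept in the matrix, listed in the report).
    Invariant-set barcodes are retained as extra rows for Level 3.
    """
    cfg = cfg or PipelineConfig()
    beads.check_panel(panel)
    med = (
        beads.records.groupby(["barcode_id", "sample_id"], sort=False)["fi"]
        .median()
        .unstack("sample_id")
    )
    gene_order = list(panel.genes["barcode_id"]) + sorted(panel.invariant_barcodes)
    sample_order = [s.sample_id for s in samples]
    med = med.reindex(index=gene_order, columns=sample_order)

    bc2g = panel.barcode_to_gene
    med.index = [bc2g.get(bc, bc) for bc in gene_order]

    n_missing = med.isna().sum(axis=0)
    for sid, k in n_missing.items():
        if k:
            (report.missing_counts if report else {})[sid] = int(k)
            logger.warning("sample %s: %d analytes with zero beads", sid, k)
        if k > cfg.max_missing_fraction * len(med):
            if report is not None:
                report.failed_samples.append(sid)
            logger.error("sample %s flagged failed: %d/%d analytes missing", sid, k, len(med))

    return ExpressionMatrix(
        values=med, samples=list(samples), level=Level.L2_MFI,
        provenance=["level2_median_collapse"],
    )


# ---------------------------------------------------------------------------
# Level 3: loess to invariant sets + quantile normalization
# ---------------------------------------------------------------------------

def _loess_fit(x_anchor: np.ndarray, y_anchor: np.ndarray, x_query: np.ndarray,
               span: float) -> np.ndarray:
    """Degree-1 tricube loess through the anchors, evaluated at x_query.

    Queries beyond the anchor range reuse the local fit at the nearest
    boundary anchor, i.e. the boundary line extended.
    """
    order = np.argsort(x_anchor)
    xa, ya = x_anchor[order], y_anchor[order]
    n = len(xa)
    k = max(2, int(np.ceil(span * n)))
    lo, hi = xa[0], xa[-1]
    xq = np.clip(x_query, lo, hi)  # fit location clamped to anchor range
    out = np.empty_like(x_query, dtype=float)
    for i, (x0, xf) in enumerate(zip(xq, x_query)):
        d = np.abs(xa - x0)
        cut = np.sort(d)[k - 1]
        if cut == 0:
            cut = max(d.max(), 1e-12)
        w = np.clip(1 - (d / cut) ** 3, 0, None) ** 3
        w[d <= cut] = np.maximum(w[d <= cut], 1e-9)  # keep window non-degenerate
        sw = w.sum()
        xm = (w * xa).sum() / sw
        ym = (w * ya).sum() / sw
        sxx = (w * (xa - xm) ** 2).sum()
        slope = (w * (xa - xm) * (ya - ym)).sum() / sxx if sxx > 0 else 0.0
        out[i] = ym + slope * (xf - xm)  # evaluate at the true x: linear extension
    return out


def _quantile_normalize(block: np.ndarray) -> np.ndarray:
    """Replace each column's k-th order statistic by the mean k-th order
    statistic across columns; tied values get the mean over their tied span."""
    n, m = block.shape
    sorted_cols = np.sort(block, axis=0)
    sorted_cols.sort(axis=1)  # fixed summation order: exactly column-permutation invariant
    target = sorted_cols.mean(axis=1)
    out = np.empty_like(block)
    for j in range(m):
        col = block[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty(n)
        i = 0
        while i < n:
            k = i
            while k + 1 < n and col[order[k + 1]] == col[order[i]]:
                k += 1
            assigned[order[i:k + 1]] = target[i:k + 1].mean()
            i = k + 1
        out[:, j] = assigned
    return out


def level3_normalize(
    m2: ExpressionMatrix,
    panel: ProbePanel,
    cfg: PipelineConfig | None = None,
    report: ProcessingReport | None = None,
) -> ExpressionMatrix:
    """Invariant-set loess normalization per well, then per-plate quantile
    normalization.

    Per well: the median MFI of each invariant set is paired with that
    set's reference level; the loess map fitted through those ten anchors
    (on the log2(x+1) scale, where they are near-equispaced) is applied to
    every measured gene's MFI.  Wells with fewer than ten usable anchors
    are excluded and logged.  Each plate's wells are then
    quantile-normalized so every well on a plate shares one empirical
    distribution; output stays on the log2 scale unless ``log_transform``
    is off.  Invariant rows are dropped from the output; only the measured
    panel remains.
    """
    cfg = cfg or PipelineConfig()
    if m2.level != Level.L2_MFI:
        raise ValueError(f"level3_normalize expects L2_MFI input, got {m2.level.value}")
    gene_rows = [g for g in panel.gene_symbols if g in m2.values.index]
    inv_sets = [
        ([b for b in members if b in m2.values.index], lvl)
        for members, lvl in panel.invariant_sets
    ]

    kept_samples, kept_cols = [], []
    for s in m2.samples:
        col = m2.values[s.sample_id]
        anchors_x, anchors_y = [], []
        for members, lvl in inv_sets:
            vals = col.loc[members].dropna()
            if len(vals):
                anchors_x.append(float(vals.median()))
                anchors_y.append(float(lvl))
        if len(anchors_x) < len(panel.invariant_sets):
            if report is not None:
                report.excluded_wells.append(s.sample_id)
            logger.warning(
                "well %s excluded: only %d/%d usable invariant anchors",
                s.sample_id, len(anchors_x), len(panel.invariant_sets),
            )
            continue
        x = col.loc[gene_rows].to_numpy(dtype=float)
        mask = np.isfinite(x)
        y = np.full_like(x, np.nan)
        # fit in log2 space: anchors are near-equispaced and near-colinear
        # there, so the wide-span local fit stays accurate at low intensity
        ax = np.log2(np.asarray(anchors_x) + 1.0)
        ay = np.log2(np.asarray(anchors_y) + 1.0)
        y[mask] = _loess_fit(ax, ay, np.log2(x[mask] + 1.0), cfg.loess_span)
        if not np.isfinite(y[mask]).all():
            raise FloatingPointError(f"non-finite loess output in well {s.sample_id}")
        kept_samples.append(s)
        kept_cols.append(y)

    values = pd.DataFrame(
        np.column_stack(kept_cols) if kept_cols else np.empty((len(gene_rows), 0)),
        index=gene_rows, columns=[s.sample_id for s in kept_samples],
    )
    if not cfg.log_transform:
        values = np.exp2(values) - 1.0  # back to the MFI scale

    # per-plate quantile normalization
    plates: dict[str, list[str]] = {}
    for s in kept_samples:
        plates.setdefault(s.plate_id, []).append(s.sample_id)
    for plate_id, cols in plates.items():
        block = values[cols].to_numpy(dtype=float)
        values[cols] = _quantile_normalize(block)

    note = "level3_normalize(loess+{}quantile)".format("log2+" if cfg.log_transform else "")
    return m2.advance(Level.L3_NORM, values, samples=kept_samples, note=note)


# ---------------------------------------------------------------------------
# Level 4: robust z-scores against the plate population
# ---------------------------------------------------------------------------

def level4_robust_zscore(
    m3: ExpressionMatrix,
    cfg: PipelineConfig | None = None,
    report: ProcessingReport | None = None,
) -> ExpressionMatrix:
    """Gene-wise robust z-scores, reference = all samples on the plate.

    z_gs = (x_gs - median_p(x_g.)) / (mad_scale * max(MAD_p(x_g.), floor)).
    Plates with fewer than 4 samples raise; all-constant genes are floored
    and logged.
    """
    cfg = cfg or PipelineConfig()
    if m3.level != Level.L3_NORM:
        raise ValueError(f"level4_robust_zscore expects L3_NORM input, got {m3.level.value}")
    plates: dict[str, list[str]] = {}
    for s in m3.samples:
        plates.setdefault(s.plate_id, []).append(s.sample_id)
    z = pd.DataFrame(index=m3.values.index, columns=m3.values.columns, dtype=float)
    for plate_id, cols in plates.items():
        if len(cols) < 4:
            raise ValueError(f"plate {plate_id} has {len(cols)} samples; need >= 4")
        block = m3.values[cols].to_numpy(dtype=float)
        med = np.nanmedian(block, axis=1, keepdims=True)
        mad = np.nanmedian(np.abs(block - med), axis=1, keepdims=True)
        floored = mad < cfg.mad_floor
        if floored.any():
            if report is not None:
                report.floored_mad_genes[plate_id] = int(floored.sum())
            logger.warning("plate %s: %d genes with MAD floored", plate_id, int(floored.sum()))
        scale = cfg.mad_scale * np.maximum(mad, cfg.mad_floor)
        z[cols] = (block - med) / scale
    return m3.advance(Level.L4_ZSCORE, z, note="level4_robust_zscore")


# ---------------------------------------------------------------------------
# Level 5: weighted replicate collapse
# ---------------------------------------------------------------------------

def replicate_weights(z_block: np.ndarray, min_weight: float = 0.01) -> np.ndarray:
    """Correlation-moderated replicate weights.

    Each replicate's raw weight is the mean of its pairwise Spearman
    correlations to the other replicates, floored at ``min_weight`` and
    normalized to sum 1.  A single replicate gets weight 1.
    """
    n = z_block.shape[1]
    if n == 1:
        return np.array([1.0])
    rho = np.asarray(stats.spearmanr(z_block).statistic, dtype=float)
    if rho.ndim == 0:  # n == 2, or a fully constant block
        rho = np.full((n, n), float(rho))
    rho = np.nan_to_num(rho, nan=0.0)  # constant replicate -> no information
    np.fill_diagonal(rho, 1.0)
    raw = (rho.sum(axis=1) - 1.0) / (n - 1)
    raw = np.maximum(raw, min_weight)
    return raw / raw.sum()


def level5_collapse(
    m4: ExpressionMatrix,
    cfg: PipelineConfig | None = None,
    report: ProcessingReport | None = None,
    groups: dict[str, list[str]] | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Collapse biological replicates into one signature per group.

    Groups default to the replicate_group metadata field (ungrouped
    samples form singleton groups).  Returns the Level 5 matrix plus a
    table with each group's replicate count and weights.
    """
    cfg = cfg or PipelineConfig()
    if m4.level != Level.L4_ZSCORE:
        raise ValueError(f"level5_collapse expects L4_ZSCORE input, got {m4.level.value}")
    by_id = {s.sample_id: s for s in m4.samples}
    if groups is None:
        groups = {}
        for s in m4.samples:
            key = s.replicate_group or s.sample_id
            groups.setdefault(key, []).append(s.sample_id)
    for g, members in groups.items():
        if not members:
            raise ValueError(f"replicate group {g!r} is empty")

    cols, metas, rows = {}, [], []
    for g in groups:
        members = groups[g]
        block = m4.values[members].to_numpy(dtype=float)
        w = replicate_weights(block, cfg.min_weight)
        cols[g] = block @ w
        first = by_id[members[0]]
        metas.append(
            SampleMeta(
                sample_id=g, plate_id=first.plate_id, well=first.well,
                cell_line=first.cell_line, sma_type=first.sma_type,
                perturbagen_id=first.perturbagen_id, dose=first.dose,
                time=first.time, replicate_group=g,
            )
        )
        rows.append({"signature_id": g, "n": len(members),
                     "weights": [round(float(x), 6) for x in w]})
        if report is not None:
            report.group_weights[g] = [float(x) for x in w]
            report.group_n[g] = len(members)

    values = pd.DataFrame(cols, index=m4.values.index)
    m5 = m4.advance(Level.L5_SIGNATURE, values, samples=metas, note="level5_collapse")
    return m5, pd.DataFrame(rows).set_index("signature_id")


def run_pipeline(
    beads: BeadTable,
    panel: ProbePanel,
    samples: list[SampleMeta],
    cfg: PipelineConfig | None = None,
) -> dict:
    """Level 1 bead table through Level 5 signatures in one call.

    Returns dict with keys level2..level5, the group table and the report.
    """
    cfg = cfg or PipelineConfig()
    report = ProcessingReport()
    m2 = level2_median_collapse(beads, panel, samples, cfg, report)
    m3 = level3_normalize(m2, panel, cfg, report)
    m4 = level4_robust_zscore(m3, cfg, report)
    m5, group_table = level5_collapse(m4, cfg, report)
    return {"level2": m2, "level3": m3, "level4": m4, "level5": m5,
            "groups": group_table, "report": report}
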
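"""Simulated bead-level screens with known ground truth.

The generator emulates the structure of a targeted Luminex screen: 384-well
plates, compounds at a few doses with biological replicates, vehicle-control
wells in fixed columns, ~30 beads per analyte, and ten invariant gene sets
at fixed, level-ordered reference expression.

Generative model for a compound-gene bead intensity in well w on plate p:

    FI = exp( baseline_g + delta_g * 1[affected] + log g_w + shift_p + eps )
    eps ~ Normal(0, sigma_bead^2)

Invariant beads track the well gain g_w around their set's reference level
but never respond to compounds — exactly the property the loess
normalization in the pipeline relies on.  Effects ``delta`` are additive on
the natural-log FI scale, so a delta of ln(2) is a 2-fold change.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    BeadTable,
    ExpressionMatrix,
    Level,
    ProbePanel,
    SampleMeta,
)

PLATE_ROWS = "ABCDEFGHIJKLMNOP"
PLATE_COLS = 24
PLATE_WELLS = len(PLATE_ROWS) * PLATE_COLS  # 384


def make_panel(
    n_genes: int = 467,
    n_invariant_sets: int = 10,
    invariant_set_size: int = 8,
    seed: int = 0,
) -> ProbePanel:
    """Build a synthetic probe panel with log-spaced invariant reference levels."""
    rng = np.random.default_rng(seed)
    genes = pd.DataFrame(
        {
            "entrez_id": np.arange(1000, 1000 + n_genes),
            "hgnc_symbol": [f"GENE{i:04d}" for i in range(n_genes)],
            "barcode_id": [f"BC{i:04d}" for i in range(n_genes)],
            "validated": True,
        }
    )
    # reference levels log-spaced over a plausible MFI range
    levels = np.exp(np.linspace(np.log(50.0), np.log(15000.0), n_invariant_sets))
    invariant_sets = []
    for s in range(n_invariant_sets):
        members = [f"INV{s}_{j}" for j in range(invariant_set_size)]
        invariant_sets.append((members, float(levels[s])))
    del rng  # reserved for future per-gene attributes
    return ProbePanel(genes=genes, invariant_sets=invariant_sets, name="synthetic")


@dataclass
class SimConfig:
    """Configuration of one simulated screen.

    Doses in µM, times in hours; ``sigma_bead`` is the bead-level log-normal
    noise SD; well gains are log-normal with SD ``sigma_well``; plates get an
    additive log-scale batch shift with SD ``sigma_plate``.  Compounds with
    index >= ``n_active`` are nulls (delta = 0).
    """

    seed: int = 0
    panel: ProbePanel | None = None
    n_plates: int = 1
    n_compounds: int = 10
    n_active: int | None = None  # default: all compounds active
    doses: tuple[float, ...] = (0.5, 5.0)
    times: tuple[float, ...] = (24.0,)
    n_replicates: int = 3
    n_vehicle_wells: int = 24
    beads_per_analyte: int = 30
    n_affected_genes: int = 20
    effect_size: float = 1.0  # |delta| on natural-log FI scale
    sigma_bead: float = 0.1
    sigma_well: float = 0.15
    sigma_plate: float = 0.1
    baseline_log_expression: np.ndarray | None = None
    cell_line: str = "NGN2_line1"
    vehicle_columns: tuple[int, ...] = (23, 24)

    def __post_init__(self):
        if self.panel is None:
            self.panel = make_panel(seed=self.seed)
        if self.n_active is None:
            self.n_active = self.n_compounds
        if self.beads_per_analyte < 1:
            raise ValueError("beads_per_analyte must be >= 1")
        if self.baseline_log_expression is None:
            rng = np.random.default_rng(self.seed + 1)
            self.baseline_log_expression = rng.uniform(
                np.log(100.0), np.log(8000.0), self.panel.size
            )
        self.baseline_log_expression = np.asarray(self.baseline_log_expression, dtype=float)
        if len(self.baseline_log_expression) != self.panel.size:
            raise ValueError("baseline vector length must equal panel size")


@dataclass
class GroundTruth:
    """Planted truth serialized alongside every simulated dataset."""

    effects: dict[tuple[str, float, float], dict[str, float]]  # (pert, dose, time) -> gene -> delta
    well_gains: dict[str, float]  # sample_id -> g_w
    plate_shifts: dict[str, float]  # plate_id -> additive log shift
    config_summary: dict = field(default_factory=dict)

    def affected_genes(self, pert: str, dose: float, time: float) -> dict[str, float]:
        return self.effects.get((pert, dose, time), {})

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "effects": [
                {"perturbagen_id": p, "dose": d, "time": t, "deltas": deltas}
                for (p, d, t), deltas in sorted(self.effects.items())
            ],
            "well_gains": self.well_gains,
            "plate_shifts": self.plate_shifts,
            "config_summary": self.config_summary,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
        return Path(path)


def _well_name(i: int) -> str:
    return f"{PLATE_ROWS[i // PLATE_COLS]}{i % PLATE_COLS + 1:02d}"


def simulate_screen(cfg: SimConfig) -> tuple[BeadTable, list[SampleMeta], GroundTruth]:
    """Generate a bead-level screen with planted compound effects.

    Vehicle wells occupy the configured fixed columns of every plate;
    treatment wells fill the remaining positions row-major.  Raises if the
    requested conditions do not fit the plate capacity.
    """
    panel = cfg.panel
    rng = np.random.default_rng(cfg.seed)

    conditions = [
        (f"CPD{c:03d}", dose, time)
        for c in range(cfg.n_compounds)
        for dose in cfg.doses
        for time in cfg.times
    ]
    n_treat = len(conditions) * cfg.n_replicates
    vehicle_idx = [
        r * PLATE_COLS + (c - 1)
        for r in range(len(PLATE_ROWS))
        for c in cfg.vehicle_columns
    ][: cfg.n_vehicle_wells]
    treat_capacity = cfg.n_plates * (PLATE_WELLS - len(vehicle_idx))
    if n_treat > treat_capacity:
        raise ValueError(
            f"layout capacity exceeded: need {n_treat} treatment wells, "
            f"have {treat_capacity} across {cfg.n_plates} plates"
        )

    # plant effects per condition; compounds beyond n_active are nulls
    effects: dict[tuple[str, float, float], dict[str, float]] = {}
    symbols = panel.gene_symbols
    for c in range(cfg.n_compounds):
        pert = f"CPD{c:03d}"
        if c < cfg.n_active:
            genes = rng.choice(panel.size, size=min(cfg.n_affected_genes, panel.size),
                               replace=False)
            signs = rng.choice([-1.0, 1.0], size=len(genes))
            deltas = {symbols[g]: float(s * cfg.effect_size) for g, s in zip(genes, signs)}
        else:
            deltas = {}
        for dose in cfg.doses:
            for time in cfg.times:
                effects[(pert, dose, time)] = deltas

    plate_shifts = {
        f"plate{p + 1}": float(rng.normal(0.0, cfg.sigma_plate)) for p in range(cfg.n_plates)
    }

    # distribute treatment wells round-robin across plates for balance
    treat_list = [
        (pert, dose, time)
        for (pert, dose, time) in conditions
        for _ in range(cfg.n_replicates)
    ]
    vehicle_set = set(vehicle_idx)
    treat_slots = [i for i in range(PLATE_WELLS) if i not in vehicle_set]
    per_plate: list[list[tuple[str, float, float]]] = [[] for _ in range(cfg.n_plates)]
    for k, cond in enumerate(treat_list):
        p = k % cfg.n_plates
        while len(per_plate[p]) >= len(treat_slots):
            p = (p + 1) % cfg.n_plates
        per_plate[p].append(cond)

    samples: list[SampleMeta] = []
    well_gains: dict[str, float] = {}
    for p in range(cfg.n_plates):
        plate_id = f"plate{p + 1}"
        assigned = iter(per_plate[p])
        for i in range(PLATE_WELLS):
            if i in vehicle_set:
                pert, dose, time = "DMSO", None, cfg.times[0]
            else:
                try:
                    pert, dose, time = next(assigned)
                except StopIteration:
                    continue
            sid = f"{plate_id}:{_well_name(i)}"
            group = "" if dose is None else f"{pert}|{dose}|{time}|{cfg.cell_line}"
            samples.append(
                SampleMeta(
                    sample_id=sid, plate_id=plate_id, well=_well_name(i),
                    cell_line=cfg.cell_line, perturbagen_id=pert,
                    dose=dose, time=time, replicate_group=group,
                )
            )
            well_gains[sid] = float(np.exp(rng.normal(0.0, cfg.sigma_well)))

    # bead generation, vectorized per sample
    inv_members = [(m, lvl) for members, lvl in panel.invariant_sets for m in members]
    inv_barcodes = [m for m, _ in inv_members]
    inv_levels = np.array([lvl for _, lvl in inv_members])
    gene_barcodes = list(panel.genes["barcode_id"])
    nb = cfg.beads_per_analyte
    n_analyte = panel.size + len(inv_barcodes)
    all_barcodes = np.array(gene_barcodes + inv_barcodes)
    barcode_col = np.repeat(all_barcodes, nb)

    frames = []
    for s in samples:
        log_gain = np.log(well_gains[s.sample_id])
        shift = plate_shifts[s.plate_id]
        mu = cfg.baseline_log_expression.copy()
        deltas = effects.get((s.perturbagen_id, s.dose, s.time), {})
        if deltas:
            idx = {g: k for k, g in enumerate(symbols)}
            for g, d in deltas.items():
                mu[idx[g]] += d
        gene_log = mu + log_gain + shift
        inv_log = np.log(inv_levels) + log_gain  # invariant beads: well gain only
        log_mu = np.concatenate([gene_log, inv_log])
        eps = (rng.normal(0.0, cfg.sigma_bead, size=(n_analyte, nb))
               if cfg.sigma_bead > 0 else np.zeros((n_analyte, nb)))
        fi = np.exp(log_mu[:, None] + eps).ravel()
        frames.append(
            pd.DataFrame({"sample_id": s.sample_id, "barcode_id": barcode_col, "fi": fi})
        )
    beads = BeadTable(records=pd.concat(frames, ignore_index=True))

    truth = GroundTruth(
        effects=effects,
        well_gains=well_gains,
        plate_shifts=plate_shifts,
        config_summary={
            "seed": cfg.seed, "n_plates": cfg.n_plates, "n_compounds": cfg.n_compounds,
            "n_active": cfg.n_active, "doses": list(cfg.doses), "times": list(cfg.times),
            "n_replicates": cfg.n_replicates, "sigma_bead": cfg.sigma_bead,
            "sigma_well": cfg.sigma_well, "sigma_plate": cfg.sigma_plate,
            "effect_size": cfg.effect_size, "panel_size": panel.size,
        },
    )
    return beads, samples, truth


def simulate_reference_expression(
    cfg: SimConfig,
    n_cell_lines: int = 96,
    probe_fidelity: np.ndarray | float = 1.0,
    n_reference_genes: int = 22_225,
    noise_sd: float = 0.0,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Paired (measured panel, large reference) baseline expression matrices.

    Emulates probe validation against a reference transcriptome: each panel
    gene has a matched row in the reference matrix; its measured vector is a
    fidelity-weighted mix of the matched row and an independent draw,

        measured_g = f_g * ref_g + (1 - f_g) * e_g + noise,

    so fidelity 1 with zero noise reproduces the reference row exactly and
    fidelity 0 is statistically independent of it.  Values are on a log2
    RPKM-like scale.
    """
    if n_cell_lines < 3:
        raise ValueError("need at least 3 cell lines")
    panel = cfg.panel
    fid = np.broadcast_to(np.asarray(probe_fidelity, dtype=float), (panel.size,)).copy()
    if ((fid < 0) | (fid > 1)).any():
        raise ValueError("probe fidelity must lie in [0, 1]")
    if n_reference_genes < panel.size:
        raise ValueError("reference must contain at least the panel genes")
    rng = np.random.default_rng(cfg.seed + 7)

    gene_means = rng.uniform(0.0, 8.0, n_reference_genes)
    ref = gene_means[:, None] + rng.normal(0.0, 1.5, (n_reference_genes, n_cell_lines))
    ref_names = panel.gene_symbols + [
        f"REF{i:05d}" for i in range(n_reference_genes - panel.size)
    ]
    cell_lines = [f"CL{j:03d}" for j in range(n_cell_lines)]

    indep = gene_means[: panel.size, None] + rng.normal(
        0.0, 1.5, (panel.size, n_cell_lines)
    )
    measured = fid[:, None] * ref[: panel.size] + (1.0 - fid[:, None]) * indep
    if noise_sd > 0:
        measured = measured + rng.normal(0.0, noise_sd, measured.shape)

    def _mat(values: np.ndarray, index: list[str]) -> ExpressionMatrix:
        metas = [
            SampleMeta(sample_id=cl, plate_id="baseline", well=_well_name(j), cell_line=cl)
            for j, cl in enumerate(cell_lines)
        ]
        return ExpressionMatrix(
            values=pd.DataFrame(values, index=index, columns=cell_lines),
            samples=metas,
            level=Level.L3_NORM,
            provenance=["simulate_reference_expression"],
        )

    return _mat(measured, panel.gene_symbols), _mat(ref, ref_names)
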
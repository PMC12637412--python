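"""Domain types and text-format I/O shared by the whole platform.

The platform moves expression data through five processing levels, from raw
bead fluorescence (Level 1) to replicate-collapsed z-score signatures
(Level 5).  Everything downstream — quality metrics, probe validation,
connectivity queries — consumes the containers defined here.

File formats: GCT 1.2/1.3 for matrices, GMT for gene sets, TSV/CSV for the
probe panel, sample metadata and DEG tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cmapneuro")

#: Panel size of the neuro probe pool; used as the TAS denominator.
NEURO_PANEL_SIZE = 467

WELL_RE = re.compile(r"^([A-P])(\d{1,2})$")


class ParseError(ValueError):
    """Malformed input file (bad header, dimension mismatch, duplicates)."""


class PanelError(ValueError):
    """Probe panel violates a structural invariant."""


def normalize_well(well: str) -> str:
    """Normalize a 384-well id to zero-padded form ('A1' -> 'A01').

    Raises ``ValueError`` for ids outside rows A-P / columns 1-24.
    """
    m = WELL_RE.match(well.strip().upper())
    if not m:
        raise ValueError(f"invalid 384-well id: {well!r}")
    row, col = m.group(1), int(m.group(2))
    if not 1 <= col <= 24:
        raise ValueError(f"well column out of range 1-24: {well!r}")
    return f"{row}{col:02d}"


class Level(str, Enum):
    """Processing level of an expression matrix. Transitions only move forward."""

    L2_MFI = "L2_MFI"
    L3_NORM = "L3_NORM"
    L4_ZSCORE = "L4_ZSCORE"
    L5_SIGNATURE = "L5_SIGNATURE"

    @property
    def order(self) -> int:
        return {"L2_MFI": 2, "L3_NORM": 3, "L4_ZSCORE": 4, "L5_SIGNATURE": 5}[self.value]


LEVEL_ORDER = [Level.L2_MFI, Level.L3_NORM, Level.L4_ZSCORE, Level.L5_SIGNATURE]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one well / profiled sample."""

    sample_id: str
    plate_id: str
    well: str
    cell_line: str = ""
    sma_type: str = "other"
    perturbagen_id: str = ""
    dose: float | None = None  # µM; None marks vehicle control
    time: float = 24.0  # hours
    replicate_group: str = ""

    def __post_init__(self):
        object.__setattr__(self, "well", normalize_well(self.well))

    @property
    def is_vehicle(self) -> bool:
        return self.dose is None


def validate_replicate_groups(samples: Sequence[SampleMeta]) -> None:
    """Samples sharing a replicate_group must share condition fields."""
    seen: dict[str, tuple] = {}
    for s in samples:
        if not s.replicate_group:
            continue
        key = (s.perturbagen_id, s.dose, s.time, s.cell_line)
        prev = seen.setdefault(s.replicate_group, key)
        if prev != key:
            raise ValueError(
                f"replicate group {s.replicate_group!r} mixes conditions {prev} and {key}"
            )


@dataclass
class ProbePanel:
    """The measured gene panel plus the ten invariant normalization sets.

    ``genes`` holds one row per measured gene (entrez_id, hgnc_symbol,
    barcode_id, validated).  ``invariant_sets`` is a list of ten
    (member barcode ids, reference level) pairs with strictly increasing
    reference levels; invariant genes carry their own barcodes, disjoint
    from the measured panel.
    """

    genes: pd.DataFrame
    invariant_sets: list[tuple[list[str], float]]
    name: str = "panel"

    def __post_init__(self):
        required = {"entrez_id", "hgnc_symbol", "barcode_id"}
        missing = required - set(self.genes.columns)
        if missing:
            raise PanelError(f"panel gene table missing columns: {sorted(missing)}")
        if "validated" not in self.genes.columns:
            self.genes = self.genes.assign(validated=True)
        self.genes = self.genes.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        barcodes = list(self.genes["barcode_id"])
        inv_barcodes = [b for members, _ in self.invariant_sets for b in members]
        all_bc = barcodes + inv_barcodes
        if len(set(all_bc)) != len(all_bc):
            dupes = sorted({b for b in all_bc if all_bc.count(b) > 1})
            raise PanelError(f"duplicate barcode ids (1:1 bead:gene violated): {dupes}")
        if len(set(self.genes["hgnc_symbol"])) != len(self.genes):
            raise PanelError("duplicate HGNC symbols in panel")
        if not self.invariant_sets:
            raise PanelError("panel has no invariant sets")
        levels = [lvl for _, lvl in self.invariant_sets]
        if not all(b > a for a, b in zip(levels, levels[1:])):
            raise PanelError(f"invariant reference levels not strictly increasing: {levels}")
        for i, (members, _) in enumerate(self.invariant_sets):
            if not members:
                raise PanelError(f"invariant set {i} is empty")

    @property
    def size(self) -> int:
        """Number of measured (non-invariant) panel genes, G."""
        return len(self.genes)

    @property
    def gene_symbols(self) -> list[str]:
        return list(self.genes["hgnc_symbol"])

    @property
    def barcode_to_gene(self) -> dict[str, str]:
        return dict(zip(self.genes["barcode_id"], self.genes["hgnc_symbol"]))

    @property
    def invariant_barcodes(self) -> set[str]:
        return {b for members, _ in self.invariant_sets for b in members}

    @property
    def all_barcodes(self) -> set[str]:
        return set(self.genes["barcode_id"]) | self.invariant_barcodes


@dataclass
class BeadTable:
    """Level 1 raw bead events: one row per (sample_id, barcode_id, fi)."""

    records: pd.DataFrame

    def __post_init__(self):
        required = {"sample_id", "barcode_id", "fi"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"bead table missing columns: {sorted(missing)}")
        if (self.records["fi"] < 0).any():
            raise ValueError("negative fluorescence intensities in bead table")

    def check_panel(self, panel: ProbePanel) -> None:
        known = panel.all_barcodes
        unknown = set(self.records["barcode_id"]) - known
        if unknown:
            raise ValueError(f"bead barcodes not in panel: {sorted(unknown)[:5]}")

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix tagged with its processing level.

    ``values`` is a DataFrame indexed by gene id with one column per
    sample id; ``samples`` carries the SampleMeta in column order;
    ``provenance`` is an append-only processing log.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    level: Level
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self):
        if list(self.values.columns) != [s.sample_id for s in self.samples]:
            raise ValueError("column order does not match sample metadata order")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def meta_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append(
                {
                    "sample_id": s.sample_id,
                    "plate_id": s.plate_id,
                    "well": s.well,
                    "cell_line": s.cell_line,
                    "sma_type": s.sma_type,
                    "perturbagen_id": s.perturbagen_id,
                    "dose": s.dose,
                    "time": s.time,
                    "replicate_group": s.replicate_group,
                }
            )
        return pd.DataFrame(rows).set_index("sample_id")

    def advance(self, new_level: Level, values: pd.DataFrame,
                samples: list[SampleMeta] | None = None, note: str = "") -> "ExpressionMatrix":
        """Produce the next-level matrix; levels must only move forward."""
        if new_level.order <= self.level.order:
            raise ValueError(f"level transition {self.level.value} -> {new_level.value} not forward")
        out = ExpressionMatrix(
            values=values,
            samples=self.samples if samples is None else samples,
            level=new_level,
            provenance=[*self.provenance, note] if note else list(self.provenance),
        )
        return out


@dataclass
class DEGTable:
    """Differential-expression results used to build query gene sets."""

    records: pd.DataFrame
    significance_kind: str = "fdr"  # or "pvalue"

    def __post_init__(self):
        required = {"gene_symbol", "log2fc", "significance"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"DEG table missing columns: {sorted(missing)}")
        if self.records["gene_symbol"].duplicated().any():
            raise ValueError("duplicate gene symbols in DEG table")
        sig = self.records["significance"]
        if ((sig < 0) | (sig > 1)).any():
            raise ValueError("significance values outside [0, 1]")
        if self.significance_kind not in ("pvalue", "fdr"):
            raise ValueError(f"unknown significance kind: {self.significance_kind}")


@dataclass(frozen=True)
class QueryGeneSets:
    """Up/down gene-symbol sets entered into a connectivity query."""

    up: frozenset[str]
    down: frozenset[str]

    def __post_init__(self):
        if not self.up or not self.down:
            raise ValueError("both up and down sets must be non-empty")
        overlap = set(self.up) & set(self.down)
        if overlap:
            raise ValueError(f"up and down sets overlap: {sorted(overlap)[:5]}")


# ---------------------------------------------------------------------------
# GCT I/O
# ---------------------------------------------------------------------------

_NA = "NA"


def write_gct(m: ExpressionMatrix, path: str | Path) -> Path:
    """Write a matrix as GCT 1.3 text.

    Sample metadata, the processing level and the provenance log are stored
    as column-metadata rows so a round-trip rebuilds the full object.
    Missing values are written as ``NA`` (0 is a legal intensity).
    Output is deterministic: identical matrices yield identical bytes.
    """
    if m.values.shape[1] == 0 or m.values.shape[0] == 0:
        raise ValueError("refusing to write an empty matrix")
    path = Path(path)
    meta = m.meta_frame()
    chd_fields = ["plate_id", "well", "cell_line", "sma_type", "perturbagen_id",
                  "dose", "time", "replicate_group", "level", "provenance"]
    nr, nc = m.values.shape
    lines = ["#1.3", f"{nr}\t{nc}\t0\t{len(chd_fields)}"]
    lines.append("\t".join(["id", *m.sample_ids]))
    prov = " | ".join(p.replace("\t", " ").replace("\n", " ") for p in m.provenance)
    for f_ in chd_fields:
        if f_ == "level":
            vals = [m.level.value] * nc
        elif f_ == "provenance":
            vals = [prov] * nc
        else:
            vals = [_fmt_meta(meta.loc[s, f_]) for s in m.sample_ids]
        lines.append("\t".join([f_, *vals]))
    arr = m.values.to_numpy()
    for i, gid in enumerate(m.gene_ids):
        cells = [_NA if not np.isfinite(v) else f"{v:.6f}" for v in arr[i]]
        lines.append("\t".join([str(gid), *cells]))
    path.write_text("\n".join(lines) + "\n")
    return path


def _fmt_meta(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return _NA
    if isinstance(v, float):
        return f"{v:g}"
    return str(v)


def read_gct(path: str | Path) -> ExpressionMatrix:
    """Read a GCT 1.2 or 1.3 text matrix.

    Declared dimensions are checked against the parsed body; mismatches,
    malformed headers and duplicate ids raise :class:`ParseError` naming
    the offending line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#1."):
        raise ParseError(f"{path}: line 1: not a GCT file (missing #1.x version)")
    version = lines[0].strip()
    try:
        dims = [int(x) for x in lines[1].split("\t")]
    except (IndexError, ValueError) as e:
        raise ParseError(f"{path}: line 2: bad dimension line") from e
    if version == "#1.2":
        if len(dims) != 2:
            raise ParseError(f"{path}: line 2: GCT 1.2 needs 2 dimensions, got {len(dims)}")
        nr, nc = dims
        nrhd, nchd = 1, 0  # Description column
    elif version == "#1.3":
        if len(dims) != 4:
            raise ParseError(f"{path}: line 2: GCT 1.3 needs 4 dimensions, got {len(dims)}")
        nr, nc, nrhd, nchd = dims
    else:
        raise ParseError(f"{path}: line 1: unsupported GCT version {version!r}")

    header = lines[2].split("\t")
    sample_ids = header[1 + nrhd:]
    if len(sample_ids) != nc:
        raise ParseError(
            f"{path}: line 3: header has {len(sample_ids)} sample columns, declared {nc}"
        )
    col_meta: dict[str, list[str]] = {}
    row0 = 3
    for j in range(nchd):
        parts = lines[row0 + j].split("\t")
        col_meta[parts[0]] = parts[1 + nrhd:]
    body = [ln for ln in lines[row0 + nchd:] if ln.strip()]
    if len(body) != nr:
        raise ParseError(
            f"{path}: line {row0 + nchd + 1}: body has {len(body)} data rows, declared {nr}"
        )
    gene_ids, data = [], []
    for k, ln in enumerate(body):
        parts = ln.split("\t")
        if len(parts) != 1 + nrhd + nc:
            raise ParseError(
                f"{path}: line {row0 + nchd + k + 1}: expected {1 + nrhd + nc} fields, "
                f"got {len(parts)}"
            )
        gene_ids.append(parts[0])
        data.append([np.nan if c == _NA or c == "" else float(c) for c in parts[1 + nrhd:]])
    if len(set(gene_ids)) != len(gene_ids):
        raise ParseError(f"{path}: duplicate gene ids in body")
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicate sample ids in header")

    values = pd.DataFrame(np.array(data, dtype=float), index=gene_ids, columns=sample_ids)
    level = Level(col_meta["level"][0]) if "level" in col_meta else Level.L2_MFI
    prov_field = col_meta.get("provenance", [""])[0]
    provenance = [p for p in prov_field.split(" | ") if p]
    samples = []
    for i, sid in enumerate(sample_ids):
        def _get(fname, default=""):
            v = col_meta.get(fname, [default] * nc)[i]
            return "" if v == _NA else v
        dose_s = _get("dose")
        samples.append(
            SampleMeta(
                sample_id=sid,
                plate_id=_get("plate_id", "plate1") or "plate1",
                well=_get("well") or _default_well(i),
                cell_line=_get("cell_line"),
                sma_type=_get("sma_type") or "other",
                perturbagen_id=_get("perturbagen_id"),
                dose=float(dose_s) if dose_s else None,
                time=float(_get("time") or 24.0),
                replicate_group=_get("replicate_group"),
            )
        )
    return ExpressionMatrix(values=values, samples=samples, level=level, provenance=provenance)


def _default_well(i: int) -> str:
    return f"{chr(ord('A') + (i // 24) % 16)}{i % 24 + 1:02d}"


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[tuple[str, list[str]]]:
    """Read a GMT gene-set file as ordered (name, members) pairs.

    Duplicate members within a set are dropped with a warning; a line with
    fewer than three fields is a parse error.
    """
    path = Path(path)
    out = []
    for lineno, ln in enumerate(path.read_text().splitlines(), start=1):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}: line {lineno}: GMT line needs >=3 fields")
        name, members = parts[0], parts[2:]
        seen, uniq = set(), []
        for g in members:
            if g in seen:
                logger.warning("gmt set %s: duplicate member %s dropped", name, g)
            else:
                seen.add(g)
                uniq.append(g)
        out.append((name, uniq))
    return out


def write_gmt(sets: Sequence[tuple[str, Sequence[str]]], path: str | Path) -> Path:
    path = Path(path)
    lines = [f"{name}\t{name}\t" + "\t".join(members) for name, members in sets]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Panel and metadata I/O
# ---------------------------------------------------------------------------

def read_panel(path: str | Path, invariant_path: str | Path | None = None) -> ProbePanel:
    """Read a probe panel table (TSV/CSV) plus its invariant-set section.

    The gene table needs columns entrez_id, hgnc_symbol, barcode_id and an
    optional boolean ``validated``.  Invariant sets live either in a second
    file or in the same file after a ``#INVARIANT`` marker, one row per
    invariant gene: set_index, barcode_id, reference_level.
    """
    path = Path(path)
    text = path.read_text()
    if "#INVARIANT" in text:
        gene_part, inv_part = text.split("#INVARIANT", 1)
        inv_lines = [ln for ln in inv_part.splitlines() if ln.strip() and not ln.startswith("#")]
    elif invariant_path is not None:
        gene_part = text
        inv_lines = [
            ln for ln in Path(invariant_path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
    else:
        raise ParseError(f"{path}: missing invariant-set section (#INVARIANT) and no separate file")

    sep = "\t" if "\t" in gene_part.splitlines()[0] else ","
    from io import StringIO

    genes = pd.read_csv(StringIO(gene_part), sep=sep)
    inv_rows = [ln.split(sep) for ln in inv_lines]
    if inv_rows and inv_rows[0][0].strip() in ("set_index", "set"):
        inv_rows = inv_rows[1:]
    sets: dict[int, tuple[list[str], float]] = {}
    for row in inv_rows:
        if len(row) < 3:
            raise ParseError(f"{path}: invariant row needs set_index, barcode_id, level: {row}")
        idx, bc, lvl = int(row[0]), row[1].strip(), float(row[2])
        members, prev = sets.get(idx, ([], lvl))
        if members and prev != lvl:
            raise ParseError(f"{path}: invariant set {idx} has conflicting reference levels")
        members.append(bc)
        sets[idx] = (members, lvl)
    invariant_sets = [sets[k] for k in sorted(sets)]
    return ProbePanel(genes=genes, invariant_sets=invariant_sets, name=path.stem)


def write_panel(panel: ProbePanel, path: str | Path) -> Path:
    path = Path(path)
    lines = ["entrez_id\thgnc_symbol\tbarcode_id\tvalidated"]
    for _, r in panel.genes.iterrows():
        lines.append(f"{r.entrez_id}\t{r.hgnc_symbol}\t{r.barcode_id}\t{r.validated}")
    lines.append("#INVARIANT")
    lines.append("set_index\tbarcode_id\treference_level")
    for i, (members, lvl) in enumerate(panel.invariant_sets):
        for bc in members:
            lines.append(f"{i}\t{bc}\t{lvl!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep=None, engine="python")
    samples = []
    for _, r in df.iterrows():
        dose = r.get("dose")
        if pd.isna(dose) or dose == "vehicle":
            dose = None
        samples.append(
            SampleMeta(
                sample_id=str(r["sample_id"]),
                plate_id=str(r["plate_id"]),
                well=str(r["well"]),
                cell_line=str(r.get("cell_line", "") or ""),
                sma_type=str(r.get("sma_type", "other") or "other"),
                perturbagen_id=str(r.get("perturbagen_id", "") or ""),
                dose=None if dose is None else float(dose),
                time=float(r.get("time", 24.0)),
                replicate_group=str(r.get("replicate_group", "") or ""),
            )
        )
    validate_replicate_groups(samples)
    return samples


def write_sample_meta(samples: Sequence[SampleMeta], path: str | Path) -> Path:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id, "plate_id": s.plate_id, "well": s.well,
                "cell_line": s.cell_line, "sma_type": s.sma_type,
                "perturbagen_id": s.perturbagen_id,
                "dose": "" if s.dose is None else s.dose,
                "time": s.time, "replicate_group": s.replicate_group,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_deg_table(path: str | Path, significance_kind: str = "fdr") -> DEGTable:
    df = pd.read_csv(path, sep=None, engine="python")
    return DEGTable(records=df, significance_kind=significance_kind)
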
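"""Domain types, file I/O and the HPV-status classification rule.

The package operates downstream of image analysis: its spatial inputs are
segmented cell tables (one row per cell, binary marker calls, micrometre
coordinates in a per-field frame with origin at the field's top-left corner)
and its transcriptomic inputs are raw count matrices from a targeted immune
panel with designated housekeeping genes.

The delimited-text dialect is fixed: comma-separated, UTF-8, ``.`` decimal.
Expression matrices may additionally be tab-separated (auto-detected).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

logger = logging.getLogger("immunotime")

TUMOR = "tumor"
STROMA = "stroma"
COMPARTMENTS = (TUMOR, STROMA)

#: μm² per mm² — densities are reported in cells/mm², coordinates are μm.
UM2_PER_MM2 = 1e6


class ImmunotimeError(Exception):
    """Base class for all package errors."""


class FormatError(ImmunotimeError):
    """A file does not conform to the expected tabular schema."""


class ValidationError(ImmunotimeError):
    """A value violates a domain invariant."""


class ConfigurationError(ImmunotimeError):
    """A rule set, pair list or config references something unknown."""


class GenerationError(ImmunotimeError):
    """The synthetic generator could not satisfy its target."""


# ---------------------------------------------------------------------------
# Marker panels
# ---------------------------------------------------------------------------

NINE_COLOR_MARKERS = ("CD68", "CD8", "FoxP3", "CD163", "CD103", "PD-1", "PD-L1", "CK")
SIX_COLOR_MARKERS = ("CTLA-4", "CD4", "CD8", "HLA-I", "CK")


@dataclass(frozen=True)
class MarkerPanel:
    """An ordered multiplex staining panel.

    The two shipped panels mirror a TSA-based mIF design: the "9-color"
    panel (8 markers + nuclear counterstain) covers cytotoxic/regulatory
    T cells, macrophage polarization and the PD-1/PD-L1 axis; the
    "6-color" panel covers CD4 help, CTLA-4 and HLA class I.
    """

    name: str
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValidationError(f"duplicate markers in panel {self.name!r}")
        canonical = {"9-color": NINE_COLOR_MARKERS, "6-color": SIX_COLOR_MARKERS}
        if self.name in canonical and set(self.markers) != set(canonical[self.name]):
            raise ValidationError(
                f"panel {self.name!r} must contain exactly {sorted(canonical[self.name])}"
            )

    @classmethod
    def nine_color(cls) -> "MarkerPanel":
        return cls("9-color", NINE_COLOR_MARKERS)

    @classmethod
    def six_color(cls) -> "MarkerPanel":
        return cls("6-color", SIX_COLOR_MARKERS)


# ---------------------------------------------------------------------------
# Cells, fields, lesions, patients
# ---------------------------------------------------------------------------


@dataclass
class CellRecord:
    """One segmented cell: position (μm), binary marker calls, compartment."""

    cell_id: str
    field_id: str
    x: float
    y: float
    marker_calls: dict[str, bool]
    compartment: str = STROMA
    phenotypes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValidationError(f"cell {self.cell_id}: non-finite coordinates")
        if self.x < 0 or self.y < 0:
            raise ValidationError(f"cell {self.cell_id}: negative coordinates")
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"cell {self.cell_id}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}"
            )


@dataclass
class FieldGeometry:
    """One imaged field: a rectangle partitioned into tumor nests and stroma.

    Nest polygons are simple and clipped to the field rectangle, so
    tumor area + stroma area = width × height by construction.
    """

    field_id: str
    width: float
    height: float
    tumor_nests: list[Polygon] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError(f"field {self.field_id}: non-positive dimensions")
        rect = self.bounds_polygon()
        clipped = []
        for poly in self.tumor_nests:
            if not poly.is_valid:
                raise ValidationError(f"field {self.field_id}: invalid nest polygon")
            inter = poly.intersection(rect)
            if not inter.is_empty:
                clipped.append(inter)
        self.tumor_nests = clipped

    def bounds_polygon(self) -> Polygon:
        return box(0.0, 0.0, self.width, self.height)

    @property
    def area_um2(self) -> float:
        return self.width * self.height

    @property
    def tumor_region(self):
        """Union of all nests (possibly empty / multi-polygon)."""
        return unary_union(self.tumor_nests) if self.tumor_nests else Polygon()

    @property
    def tumor_area_um2(self) -> float:
        return self.tumor_region.area

    @property
    def stroma_area_um2(self) -> float:
        return self.area_um2 - self.tumor_area_um2


@dataclass
class LesionSample:
    """All imaged fields and segmented cells of one lesion of one patient."""

    sample_id: str
    patient_id: str
    lesion_type: str  # "primary" | "metastasis"
    fields: list[FieldGeometry]
    cells: list[CellRecord]

    def __post_init__(self) -> None:
        if self.lesion_type not in ("primary", "metastasis"):
            raise ValidationError(f"unknown lesion_type {self.lesion_type!r}")
        if not self.fields:
            raise ValidationError(f"sample {self.sample_id}: needs ≥1 field")
        known = {f.field_id for f in self.fields}
        for cell in self.cells:
            if cell.field_id not in known:
                raise ValidationError(
                    f"sample {self.sample_id}: cell {cell.cell_id} references "
                    f"unknown field {cell.field_id!r}"
                )

    def field_map(self) -> dict[str, FieldGeometry]:
        return {f.field_id: f for f in self.fields}

    def to_frame(self, panel: MarkerPanel | None = None) -> pd.DataFrame:
        """Tabular view: one row per cell, one 0/1 column per marker."""
        markers: Sequence[str]
        if panel is not None:
            markers = panel.markers
        else:
            markers = sorted({m for c in self.cells for m in c.marker_calls})
        n = len(self.cells)
        data = {
            "cell_id": [c.cell_id for c in self.cells],
            "field_id": [c.field_id for c in self.cells],
            "x_um": np.fromiter((c.x for c in self.cells), float, n),
            "y_um": np.fromiter((c.y for c in self.cells), float, n),
            "compartment": [c.compartment for c in self.cells],
        }
        for m in markers:
            data[m] = np.fromiter(
                (bool(c.marker_calls.get(m, False)) for c in self.cells), bool, n
            )
        return pd.DataFrame(data)

    @property
    def tumor_area_mm2(self) -> float:
        return sum(f.tumor_area_um2 for f in self.fields) / UM2_PER_MM2

    @property
    def stroma_area_mm2(self) -> float:
        return sum(f.stroma_area_um2 for f in self.fields) / UM2_PER_MM2


@dataclass
class PatientRecord:
    """HPV status, sex, clinicopathologic covariates and DFS follow-up."""

    patient_id: str
    hpv_status: str  # "positive" | "negative"
    sex: str  # "female" | "male"
    dfs_time: float  # months
    dfs_event: bool
    covariates: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.hpv_status not in ("positive", "negative"):
            raise ValidationError(f"unknown hpv_status {self.hpv_status!r}")
        if self.sex not in ("female", "male"):
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.dfs_time < 0:
            raise ValidationError("dfs_time must be ≥ 0")


# ---------------------------------------------------------------------------
# Expression matrices and signatures
# ---------------------------------------------------------------------------

SCALES = ("raw_counts", "normalized", "log2")


@dataclass
class ExpressionMatrix:
    """Gene × sample values with housekeeping flags and an explicit scale.

    ``values`` is a genes × samples DataFrame (gene names as index).
    """

    values: pd.DataFrame
    housekeeping: frozenset[str]
    scale: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate gene names: {dup}")
        missing = self.housekeeping - set(self.values.index)
        if missing:
            raise ValidationError(
                f"housekeeping genes absent from matrix: {sorted(missing)}"
            )
        if self.scale in ("raw_counts", "normalized") and (self.values.values < 0).any():
            raise ValidationError(f"negative values on {self.scale} scale")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def endogenous(self) -> list[str]:
        return [g for g in self.values.index if g not in self.housekeeping]

    def with_values(self, values: pd.DataFrame, scale: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, housekeeping=self.housekeeping, scale=scale)


@dataclass(frozen=True)
class SignatureSet:
    """A named gene list used for cell-type or pathway scoring."""

    name: str
    kind: str  # "cell_type" | "pathway"
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("cell_type", "pathway"):
            raise ValidationError(f"signature {self.name}: unknown kind {self.kind!r}")
        if not self.genes:
            raise ValidationError(f"signature {self.name}: empty gene list")


@dataclass
class AnalysisConfig:
    """Tunable analysis thresholds.

    proximity_radius
        Radius of the count-within statistic, μm (closed ball).
    median_tie_rule
        How values equal to the median dichotomize; the only shipped rule
        assigns them to the low group.
    deg_log2fc_threshold / deg_alpha
        DEG calling: |log2 fold change| strictly above the threshold and
        BH-adjusted p below alpha.
    """

    proximity_radius: float = 20.0
    median_tie_rule: str = "le_median_is_low"
    deg_log2fc_threshold: float = 1.0
    deg_alpha: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.proximity_radius <= 0:
            raise ValidationError("proximity_radius must be > 0")
        if not (0 < self.deg_alpha < 1):
            raise ValidationError("deg_alpha must be in (0, 1)")
        if self.median_tie_rule != "le_median_is_low":
            raise ValidationError(f"unknown median_tie_rule {self.median_tie_rule!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.__dict__, fh)


# ---------------------------------------------------------------------------
# HPV status
# ---------------------------------------------------------------------------


def classify_hpv_status(hpv_dna_positive: bool, p16_percent_stained: float) -> str:
    """Classify a tumor as HPV-driven.

    Positive requires double positivity: detectable HPV DNA *and* diffuse
    p16^INK4a immunostaining in at least 70% of tumor cells (inclusive
    threshold).
    """
    if not (0 <= p16_percent_stained <= 100):
        raise ValidationError(
            f"p16 staining percentage {p16_percent_stained} outside [0, 100]"
        )
    return "positive" if (hpv_dna_positive and p16_percent_stained >= 70) else "negative"


# ---------------------------------------------------------------------------
# Cell-table I/O
# ---------------------------------------------------------------------------

_CELL_COLUMNS = ("cell_id", "field_id", "x_um", "y_um", "compartment")


def read_cell_table(path: str | Path, panel: MarkerPanel) -> list[CellRecord]:
    """Read a segmented-cell CSV into validated :class:`CellRecord` rows.

    Required columns: cell_id, field_id, x_um, y_um, compartment, plus one
    0/1 column per panel marker. Unknown extra columns are ignored with a
    logged warning. Row order is preserved.
    """
    df = pd.read_csv(path, dtype={"cell_id": str, "field_id": str},
                     float_precision="round_trip")
    required = list(_CELL_COLUMNS) + list(panel.markers)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring unknown columns %s", path, extra)

    for col in ("x_um", "y_um"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.values)[0]) + 2  # 1-based + header
            raise FormatError(f"{path}: non-numeric {col} at line {row}")
        df[col] = vals

    cells: list[CellRecord] = []
    marker_arrays = {}
    for m in panel.markers:
        arr = df[m].to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValidationError(f"{path}: marker column {m!r} has values outside {{0,1}}")
        marker_arrays[m] = arr.astype(bool)
    for i in range(len(df)):
        cells.append(
            CellRecord(
                cell_id=str(df["cell_id"].iat[i]),
                field_id=str(df["field_id"].iat[i]),
                x=float(df["x_um"].iat[i]),
                y=float(df["y_um"].iat[i]),
                marker_calls={m: bool(marker_arrays[m][i]) for m in panel.markers},
                compartment=str(df["compartment"].iat[i]),
            )
        )
    return cells


def write_cell_table(
    cells: Sequence[CellRecord], panel: MarkerPanel, path: str | Path
) -> None:
    """Write cells in the dialect :func:`read_cell_table` accepts."""
    rows = []
    for c in cells:
        missing = [m for m in panel.markers if m not in c.marker_calls]
        if missing:
            raise ValidationError(
                f"cell {c.cell_id}: missing calls for panel markers {missing}"
            )
        row = {
            "cell_id": c.cell_id,
            "field_id": c.field_id,
            "x_um": c.x,
            "y_um": c.y,
            "compartment": c.compartment,
        }
        for m in panel.markers:
            row[m] = int(c.marker_calls[m])
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(_CELL_COLUMNS) + list(panel.markers))
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Expression-matrix I/O
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path: str | Path, housekeeping_path: str | Path
) -> ExpressionMatrix:
    """Read a raw genes × samples count matrix plus a housekeeping list.

    The matrix is comma- or tab-separated with gene names in the first
    column; the housekeeping file lists one gene per line.
    """
    with open(path, encoding="utf-8") as fh:
        sep = "\t" if "\t" in fh.readline() else ","
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    with open(housekeeping_path, encoding="utf-8") as fh:
        hk = frozenset(line.strip() for line in fh if line.strip())
    return ExpressionMatrix(values=df.astype(float), housekeeping=hk, scale="raw_counts")


def write_expression_matrix(
    matrix: ExpressionMatrix, path: str | Path, housekeeping_path: str | Path | None = None
) -> None:
    matrix.values.to_csv(path)
    if housekeeping_path is not None:
        with open(housekeeping_path, "w", encoding="utf-8") as fh:
            for g in sorted(matrix.housekeeping):
                fh.write(g + "\n")


# ---------------------------------------------------------------------------
# Signature-set and metadata I/O
# ---------------------------------------------------------------------------


def read_signature_sets(path: str | Path) -> list[SignatureSet]:
    """Read signatures from YAML: a list of {name, kind, genes} mappings."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    sets = []
    names = set()
    for entry in data:
        genes = entry["genes"]
        if isinstance(genes, str):
            genes = [g.strip() for g in genes.split(",") if g.strip()]
        sig = SignatureSet(name=entry["name"], kind=entry["kind"], genes=tuple(genes))
        if sig.name in names:
            raise ValidationError(f"duplicate signature name {sig.name!r}")
        names.add(sig.name)
        sets.append(sig)
    return sets


def write_signature_sets(sets: Iterable[SignatureSet], path: str | Path) -> None:
    data = [{"name": s.name, "kind": s.kind, "genes": list(s.genes)} for s in sets]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh)


def read_patient_table(path: str | Path) -> list[PatientRecord]:
    """Read patient metadata CSV (patient_id, hpv_status, sex, dfs_time_months,
    dfs_event, plus free covariate columns)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    required = ("patient_id", "hpv_status", "sex", "dfs_time_months", "dfs_event")
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    extra = [c for c in df.columns if c not in required]
    out = []
    for _, row in df.iterrows():
        out.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                hpv_status=str(row["hpv_status"]),
                sex=str(row["sex"]),
                dfs_time=float(row["dfs_time_months"]),
                dfs_event=bool(row["dfs_event"]),
                covariates={c: str(row[c]) for c in extra if pd.notna(row[c])},
            )
        )
    return out


def write_patient_table(patients: Sequence[PatientRecord], path: str | Path) -> None:
    extra = sorted({k for p in patients for k in p.covariates})
    rows = []
    for p in patients:
        row = {
            "patient_id": p.patient_id,
            "hpv_status": p.hpv_status,
            "sex": p.sex,
            "dfs_time_months": p.dfs_time,
            "dfs_event": int(p.dfs_event),
        }
        for k in extra:
            row[k] = p.covariates.get(k, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
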
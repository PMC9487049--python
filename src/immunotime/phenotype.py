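"""Phenotype assignment from marker calls and compartment assignment from geometry.

A phenotype rule is a conjunction of required-positive and required-negative
marker calls. Labels are non-exclusive: one cell can be simultaneously CD8+,
CD8+CD103+ and CD8+CD103+PD-1+ — downstream percentage denominators rely on
this subset structure rather than on exclusive gating.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import yaml

from .io import (
    STROMA,
    TUMOR,
    CellRecord,
    ConfigurationError,
    FieldGeometry,
    LesionSample,
    MarkerPanel,
    ValidationError,
)

logger = logging.getLogger("immunotime")


@dataclass(frozen=True)
class PhenotypeRule:
    """label ⇔ all ``required_positive`` called AND none of ``required_negative``."""

    label: str
    required_positive: frozenset[str]
    required_negative: frozenset[str]
    panel: MarkerPanel

    def __post_init__(self) -> None:
        if self.required_positive & self.required_negative:
            raise ValidationError(
                f"rule {self.label}: a marker cannot be required both + and −"
            )
        unknown = (self.required_positive | self.required_negative) - set(
            self.panel.markers
        )
        if unknown:
            raise ValidationError(
                f"rule {self.label}: markers {sorted(unknown)} not in panel "
                f"{self.panel.name!r}"
            )

    def matches(self, calls: dict[str, bool]) -> bool:
        return all(calls.get(m, False) for m in self.required_positive) and not any(
            calls.get(m, False) for m in self.required_negative
        )

    def refines(self, parent: "PhenotypeRule") -> bool:
        """True if every cell matching this rule necessarily matches ``parent``."""
        return parent.required_positive <= self.required_positive and (
            parent.required_negative <= self.required_negative
        )


def _rule(panel: MarkerPanel, label: str, pos: tuple[str, ...], neg: tuple[str, ...] = ()):
    return PhenotypeRule(label, frozenset(pos), frozenset(neg), panel)


def default_rules(panel: MarkerPanel) -> list[PhenotypeRule]:
    """Shipped rule set for the two mIF panels.

    Notes on deliberate choices: Treg is FoxP3+ CD8− (avoids double-counting
    FoxP3-expressing activated CTL); Th is CD4+ CK− (excludes CK/CD4
    co-staining artifacts). Both are configuration, not inference.
    """
    if panel.name == "9-color":
        return [
            _rule(panel, "tumor", ("CK",)),
            _rule(panel, "CD8+", ("CD8",)),
            _rule(panel, "FoxP3+", ("FoxP3",), ("CD8",)),
            _rule(panel, "CD68+", ("CD68",)),
            _rule(panel, "CD68+CD163+", ("CD68", "CD163")),
            _rule(panel, "CD68+CD163-", ("CD68",), ("CD163",)),
            _rule(panel, "CD8+CD103+", ("CD8", "CD103")),
            _rule(panel, "CD8+PD-1+", ("CD8", "PD-1")),
            _rule(panel, "CD8+CD103+PD-1+", ("CD8", "CD103", "PD-1")),
            _rule(panel, "PD-L1+", ("PD-L1",)),
            _rule(panel, "PD-L1+tumor", ("CK", "PD-L1")),
            _rule(panel, "CD68+CD163-PD-L1+", ("CD68", "PD-L1"), ("CD163",)),
            _rule(panel, "CD68+CD163+PD-L1+", ("CD68", "CD163", "PD-L1")),
        ]
    if panel.name == "6-color":
        return [
            _rule(panel, "tumor", ("CK",)),
            _rule(panel, "CD8+", ("CD8",)),
            _rule(panel, "CD4+", ("CD4",), ("CK",)),
            _rule(panel, "CTLA-4+T", ("CTLA-4",), ("CK",)),
            _rule(panel, "CD4+CTLA-4+", ("CD4", "CTLA-4"), ("CK",)),
            _rule(panel, "HLA-I-tumor", ("CK",), ("HLA-I",)),
        ]
    raise ConfigurationError(f"no default rules for panel {panel.name!r}")


def read_rules(path, panel: MarkerPanel) -> list[PhenotypeRule]:
    """Read a rule set from YAML: list of {label, positives, negatives}."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return [
        PhenotypeRule(
            label=entry["label"],
            required_positive=frozenset(entry.get("positives", [])),
            required_negative=frozenset(entry.get("negatives", [])),
            panel=panel,
        )
        for entry in data
    ]


def write_rules(rules, path) -> None:
    data = [
        {
            "label": r.label,
            "positives": sorted(r.required_positive),
            "negatives": sorted(r.required_negative),
        }
        for r in rules
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh)


# ---------------------------------------------------------------------------
# Assignment
# ---------------------------------------------------------------------------


def assign_phenotypes(cell: CellRecord, rules: list[PhenotypeRule]) -> set[str]:
    """Every label whose rule the cell's calls satisfy (non-exclusive)."""
    for r in rules:
        missing = (r.required_positive | r.required_negative) - set(cell.marker_calls)
        if missing:
            raise ConfigurationError(
                f"rule {r.label}: cell {cell.cell_id} has no call for {sorted(missing)}"
            )
    return {r.label for r in rules if r.matches(cell.marker_calls)}


def label_matrix(sample: LesionSample, rules: list[PhenotypeRule]) -> pd.DataFrame:
    """Vectorized rule evaluation: one boolean column per label.

    Also carries field_id, x_um, y_um, compartment for downstream use.
    """
    if not rules:
        raise ConfigurationError("empty rule set")
    panel = rules[0].panel
    frame = sample.to_frame(panel)
    out = frame[["cell_id", "field_id", "x_um", "y_um", "compartment"]].copy()
    for r in rules:
        mask = np.ones(len(frame), dtype=bool)
        for m in r.required_positive:
            if m not in frame.columns:
                raise ConfigurationError(f"rule {r.label}: marker {m!r} not in table")
            mask &= frame[m].to_numpy()
        for m in r.required_negative:
            if m not in frame.columns:
                raise ConfigurationError(f"rule {r.label}: marker {m!r} not in table")
            mask &= ~frame[m].to_numpy()
        out[r.label] = mask
    return out


def apply_phenotypes(sample: LesionSample, rules: list[PhenotypeRule]) -> None:
    """Fill every cell's ``phenotypes`` set in place."""
    lm = label_matrix(sample, rules)
    labels = [r.label for r in rules]
    bools = lm[labels].to_numpy()
    for i, cell in enumerate(sample.cells):
        cell.phenotypes = {lab for j, lab in enumerate(labels) if bools[i, j]}


# ---------------------------------------------------------------------------
# Compartments
# ---------------------------------------------------------------------------


def assign_compartment(cell: CellRecord, geometry: FieldGeometry) -> str:
    """Tumor iff the cell centre lies inside or on the boundary of any nest."""
    if cell.field_id != geometry.field_id:
        raise ValidationError(
            f"cell {cell.cell_id} field {cell.field_id!r} ≠ geometry "
            f"{geometry.field_id!r}"
        )
    if not (0 <= cell.x <= geometry.width and 0 <= cell.y <= geometry.height):
        raise ValidationError(
            f"cell {cell.cell_id} at ({cell.x}, {cell.y}) outside field rectangle"
        )
    region = geometry.tumor_region
    # intersects is boundary-inclusive; contains is not
    return TUMOR if (not region.is_empty and shapely.intersects_xy(region, cell.x, cell.y)) else STROMA


def assign_compartments(sample: LesionSample) -> None:
    """Assign every cell's compartment from its field's nest geometry (in place)."""
    fmap = sample.field_map()
    by_field: dict[str, list[int]] = {}
    for i, c in enumerate(sample.cells):
        by_field.setdefault(c.field_id, []).append(i)
    for fid, idx in by_field.items():
        geom = fmap[fid]
        xs = np.array([sample.cells[i].x for i in idx])
        ys = np.array([sample.cells[i].y for i in idx])
        if ((xs < 0) | (xs > geom.width) | (ys < 0) | (ys > geom.height)).any():
            raise ValidationError(f"field {fid}: cells outside field rectangle")
        region = geom.tumor_region
        if region.is_empty:
            inside = np.zeros(len(idx), dtype=bool)
        else:
            inside = shapely.intersects_xy(region, xs, ys)
        for k, i in enumerate(idx):
            sample.cells[i].compartment = TUMOR if inside[k] else STROMA


def phenotype_counts(
    sample: LesionSample, rules: list[PhenotypeRule] | None = None
) -> pd.DataFrame:
    """Long-format counts: one row per (phenotype, compartment) plus totals.

    If ``rules`` is omitted, counts use the phenotype sets already stored on
    the cells.
    """
    if rules is not None:
        lm = label_matrix(sample, rules)
        labels = [r.label for r in rules]
    else:
        labels = sorted({p for c in sample.cells for p in c.phenotypes})
        lm = pd.DataFrame(
            {
                "compartment": [c.compartment for c in sample.cells],
                **{
                    lab: [lab in c.phenotypes for c in sample.cells]
                    for lab in labels
                },
            }
        )
    rows = []
    for lab in labels:
        in_lab = lm[lm[lab]] if len(lm) else lm
        t = int((in_lab["compartment"] == TUMOR).sum()) if len(lm) else 0
        s = int((in_lab["compartment"] == STROMA).sum()) if len(lm) else 0
        rows.append({"sample_id": sample.sample_id, "phenotype": lab, "compartment": TUMOR, "count": t})
        rows.append({"sample_id": sample.sample_id, "phenotype": lab, "compartment": STROMA, "count": s})
        rows.append({"sample_id": sample.sample_id, "phenotype": lab, "compartment": "both", "count": t + s})
    return pd.DataFrame(rows, columns=["sample_id", "phenotype", "compartment", "count"])
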
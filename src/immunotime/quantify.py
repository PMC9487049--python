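"""Per-sample densities (cells/mm²), percentages among parent populations,
and population ratios, by compartment.

Aggregation pools cells and compartment areas across all fields of a lesion
(total count / total area), rather than averaging per-field values; this is
robust to empty fields and consistent with count-based ratios.

Zero-denominator results propagate as ``NaN`` ("missing") and are logged;
they are never silently reported as 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import (
    STROMA,
    TUMOR,
    UM2_PER_MM2,
    ImmunotimeError,
    LesionSample,
    ValidationError,
)
from .phenotype import PhenotypeRule, label_matrix

logger = logging.getLogger("immunotime")

_SCOPES = (TUMOR, STROMA, "both")


def _check_scope(compartment: str) -> None:
    if compartment not in _SCOPES:
        raise ValidationError(f"unknown compartment scope {compartment!r}")


def _count(lm: pd.DataFrame, label: str, compartment: str) -> int:
    if label not in lm.columns:
        raise ValidationError(f"unknown phenotype label {label!r}")
    mask = lm[label].to_numpy()
    if compartment != "both":
        mask = mask & (lm["compartment"] == compartment).to_numpy()
    return int(mask.sum())


def _area_mm2(sample: LesionSample, compartment: str) -> float:
    if compartment == TUMOR:
        return sample.tumor_area_mm2
    if compartment == STROMA:
        return sample.stroma_area_mm2
    return sample.tumor_area_mm2 + sample.stroma_area_mm2


def density(
    sample: LesionSample,
    rules: list[PhenotypeRule],
    phenotype: str,
    compartment: str = "both",
) -> float:
    """Pooled density: total phenotype count / total compartment area (mm²)."""
    _check_scope(compartment)
    lm = label_matrix(sample, rules)
    count = _count(lm, phenotype, compartment)
    area = _area_mm2(sample, compartment)
    if area <= 0:
        if count > 0:
            raise ImmunotimeError(
                f"sample {sample.sample_id}: {count} cells in zero-area "
                f"compartment {compartment!r}"
            )
        logger.warning(
            "sample %s: zero %s area and zero count — density undefined",
            sample.sample_id,
            compartment,
        )
        return float("nan")
    return count / area


def percentage_among_parent(
    sample: LesionSample,
    rules: list[PhenotypeRule],
    child: str,
    parent: str,
    compartment: str = "both",
) -> float:
    """100 × child count / parent count; NaN when the parent count is 0.

    The child rule must refine the parent rule (so the result is a true
    sub-population percentage in [0, 100]).
    """
    _check_scope(compartment)
    rmap = {r.label: r for r in rules}
    if child not in rmap or parent not in rmap:
        raise ValidationError(f"unknown label among ({child!r}, {parent!r})")
    if not rmap[child].refines(rmap[parent]):
        raise ValidationError(f"{child!r} is not a refinement of {parent!r}")
    lm = label_matrix(sample, rules)
    n_parent = _count(lm, parent, compartment)
    if n_parent == 0:
        logger.warning(
            "sample %s: no %s cells in %s — percentage undefined",
            sample.sample_id,
            parent,
            compartment,
        )
        return float("nan")
    return 100.0 * _count(lm, child, compartment) / n_parent


def population_ratio(
    sample: LesionSample,
    rules: list[PhenotypeRule],
    numerator: str,
    denominator: str,
    compartment: str = "both",
) -> float:
    """Count ratio between two populations; NaN when the denominator is 0."""
    _check_scope(compartment)
    lm = label_matrix(sample, rules)
    n_den = _count(lm, denominator, compartment)
    if n_den == 0:
        logger.warning(
            "sample %s: no %s cells in %s — ratio undefined",
            sample.sample_id,
            denominator,
            compartment,
        )
        return float("nan")
    return _count(lm, numerator, compartment) / n_den


def density_profile(sample: LesionSample, rules: list[PhenotypeRule]) -> pd.DataFrame:
    """Tidy table: sample_id, phenotype, compartment, count, area_mm2, density."""
    lm = label_matrix(sample, rules)
    areas = {c: _area_mm2(sample, c) for c in _SCOPES}
    rows = []
    for r in rules:
        for comp in _SCOPES:
            count = _count(lm, r.label, comp)
            area = areas[comp]
            dens = count / area if area > 0 else float("nan")
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "phenotype": r.label,
                    "compartment": comp,
                    "count": count,
                    "area_mm2": area,
                    "density_per_mm2": dens,
                }
            )
    return pd.DataFrame(rows)
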
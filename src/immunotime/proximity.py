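"""Spatial proximity statistics between phenotype populations.

Two statistics, both computed per field and pooled per lesion:

``nn_mean_distance``
    For each reference cell, the Euclidean centre-to-centre distance to the
    nearest query-phenotype cell in the *same field*; summarized as the mean
    over all reference cells whose field contains ≥1 query cell.

``pct_within_radius``
    The percentage of reference cells having at least one query cell within
    a closed ball of the given radius (default 20 μm, boundary inclusive).

Conventions: distances never cross field boundaries; a cell carrying both
the reference and the query label never counts as its own neighbor; the
compartment scope filters reference cells only (query cells are taken
field-wide); no edge correction is applied, so neighborhoods truncated by
the field border bias both statistics (documented negative bias for
``pct_within_radius``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io import STROMA, TUMOR, ConfigurationError, LesionSample, ValidationError
from .phenotype import PhenotypeRule, label_matrix

logger = logging.getLogger("immunotime")

_SCOPES = (TUMOR, STROMA, "both")


@dataclass
class ProximityResult:
    sample_id: str
    reference: str
    query: str
    compartment: str
    statistic: str  # "nn_mean_distance_um" | "pct_within_radius"
    value: float
    n_reference: int
    n_query: int
    radius_um: float | None = None
    n_reference_excluded: int = 0  # refs in fields with no query cell (NN only)


def _field_arrays(lm: pd.DataFrame, reference: str, query: str, compartment: str):
    """Yield (ref_xy, ref_idx, qry_xy, qry_idx) per field."""
    if reference not in lm.columns or query not in lm.columns:
        raise ConfigurationError(f"unknown label among ({reference!r}, {query!r})")
    if compartment not in _SCOPES:
        raise ValidationError(f"unknown compartment scope {compartment!r}")
    ref_mask = lm[reference].to_numpy()
    if compartment != "both":
        ref_mask = ref_mask & (lm["compartment"] == compartment).to_numpy()
    qry_mask = lm[query].to_numpy()
    xy = lm[["x_um", "y_um"]].to_numpy(float)
    fields = lm["field_id"].to_numpy()
    for fid in pd.unique(fields):
        in_field = fields == fid
        r = np.flatnonzero(in_field & ref_mask)
        q = np.flatnonzero(in_field & qry_mask)
        yield xy[r], r, xy[q], q


def _nearest_distances(
    ref_xy: np.ndarray, ref_idx: np.ndarray, qry_xy: np.ndarray, qry_idx: np.ndarray
) -> np.ndarray:
    """Per-reference distance to nearest query cell, excluding self-matches.

    NaN where no eligible query cell exists. A KD-tree proposes candidate
    neighbors; distances are then recomputed with plain vectorized
    arithmetic so the result is identical to a brute-force scan.
    """
    out = np.full(len(ref_idx), np.nan)
    if len(qry_idx) == 0 or len(ref_idx) == 0:
        return out
    tree = cKDTree(qry_xy)
    k = min(8, len(qry_idx))
    _, cand = tree.query(ref_xy, k=k)
    cand = np.atleast_2d(cand.reshape(len(ref_idx), -1))
    for i in range(len(ref_idx)):
        cols = cand[i]
        keep = qry_idx[cols] != ref_idx[i]
        cols = cols[keep]
        if len(cols) == 0:
            # reference coincides with the only query cell(s) in candidates;
            # fall back to a full scan minus self
            cols = np.flatnonzero(qry_idx != ref_idx[i])
            if len(cols) == 0:
                continue
        d = np.sqrt(((qry_xy[cols] - ref_xy[i]) ** 2).sum(axis=1))
        out[i] = d.min()
    return out


def nn_mean_distance(
    sample: LesionSample,
    rules: list[PhenotypeRule],
    reference: str,
    query: str,
    compartment: str = "both",
    *,
    lm: pd.DataFrame | None = None,
) -> float:
    """Mean nearest-neighbor distance (μm); NaN when undefined.

    References in fields lacking any query cell are excluded from the mean
    (not assigned an infinite distance); the exclusion is logged.
    """
    value, _, _, _ = nn_mean_distance_detail(
        sample, rules, reference, query, compartment, lm=lm
    )
    return value


def nn_mean_distance_detail(
    sample, rules, reference, query, compartment="both", *, lm=None
):
    """(mean distance, n_reference, n_query, n_excluded)."""
    if lm is None:
        lm = label_matrix(sample, rules)
    dists: list[np.ndarray] = []
    n_ref = n_qry = n_excl = 0
    for ref_xy, ref_idx, qry_xy, qry_idx in _field_arrays(lm, reference, query, compartment):
        n_ref += len(ref_idx)
        n_qry += len(qry_idx)
        d = _nearest_distances(ref_xy, ref_idx, qry_xy, qry_idx)
        n_excl += int(np.isnan(d).sum())
        dists.append(d[~np.isnan(d)])
    if n_ref == 0:
        logger.warning("sample %s: no %s reference cells", sample.sample_id, reference)
        return float("nan"), 0, n_qry, 0
    if n_excl:
        logger.warning(
            "sample %s: %d/%d %s references in fields without %s cells excluded "
            "from NN mean",
            sample.sample_id,
            n_excl,
            n_ref,
            reference,
            query,
        )
    pooled = np.concatenate(dists) if dists else np.array([])
    value = float(pooled.mean()) if len(pooled) else float("nan")
    return value, n_ref, n_qry, n_excl


def pct_within_radius(
    sample: LesionSample,
    rules: list[PhenotypeRule],
    reference: str,
    query: str,
    radius: float = 20.0,
    compartment: str = "both",
    *,
    lm: pd.DataFrame | None = None,
) -> float:
    """Percentage of reference cells with ≥1 query cell at distance ≤ radius."""
    value, _, _ = pct_within_radius_detail(
        sample, rules, reference, query, radius, compartment, lm=lm
    )
    return value


def pct_within_radius_detail(
    sample, rules, reference, query, radius=20.0, compartment="both", *, lm=None
):
    """(percentage, n_reference, n_query)."""
    if radius <= 0:
        raise ValidationError("radius must be > 0")
    if lm is None:
        lm = label_matrix(sample, rules)
    n_ref = n_qry = n_hit = 0
    for ref_xy, ref_idx, qry_xy, qry_idx in _field_arrays(lm, reference, query, compartment):
        n_ref += len(ref_idx)
        n_qry += len(qry_idx)
        if len(ref_idx) == 0 or len(qry_idx) == 0:
            continue
        tree = cKDTree(qry_xy)
        # pad the search radius, then confirm with exact arithmetic so the
        # inclusive boundary matches a brute-force scan bit for bit
        neighbors = tree.query_ball_point(ref_xy, r=radius * (1 + 1e-9))
        for i, cols in enumerate(neighbors):
            cols = np.asarray(cols, dtype=int)
            cols = cols[qry_idx[cols] != ref_idx[i]]
            if len(cols) == 0:
                continue
            d = np.sqrt(((qry_xy[cols] - ref_xy[i]) ** 2).sum(axis=1))
            if (d <= radius).any():
                n_hit += 1
    if n_ref == 0:
        logger.warning("sample %s: no %s reference cells", sample.sample_id, reference)
        return float("nan"), 0, n_qry
    return 100.0 * n_hit / n_ref, n_ref, n_qry


# ---------------------------------------------------------------------------
# Panel driver
# ---------------------------------------------------------------------------

#: (reference, query, compartment scopes) pairs mirroring the figure panels:
#: tumor↔CD8 subsets, M2-TAM↔CD8, Treg↔CD8, and the PD-L1/PD-1 axis.
DEFAULT_PAIRS: list[tuple[str, str, tuple[str, ...]]] = [
    ("tumor", "CD8+", ("both",)),
    ("tumor", "CD8+CD103+", ("both",)),
    ("tumor", "CD8+PD-1+", ("both",)),
    ("CD68+CD163+", "CD8+", (TUMOR, STROMA)),
    ("FoxP3+", "CD8+", (TUMOR, STROMA)),
    ("PD-L1+tumor", "CD8+PD-1+", ("both",)),
    ("CD68+CD163-PD-L1+", "CD8+PD-1+", (TUMOR, STROMA)),
    ("CD68+CD163+PD-L1+", "CD8+PD-1+", (TUMOR, STROMA)),
]


def default_pair_list() -> list[tuple[str, str, tuple[str, ...]]]:
    return [tuple(p) for p in DEFAULT_PAIRS]


def proximity_panel(
    sample: LesionSample,
    rules: list[PhenotypeRule],
    pairs: list[tuple[str, str, tuple[str, ...]]] | None = None,
    radius: float = 20.0,
) -> list[ProximityResult]:
    """Both statistics for every requested (reference, query, compartment)."""
    if pairs is None:
        pairs = default_pair_list()
    lm = label_matrix(sample, rules)
    results: list[ProximityResult] = []
    for reference, query, scopes in pairs:
        for comp in scopes:
            mean_d, n_ref, n_qry, n_excl = nn_mean_distance_detail(
                sample, rules, reference, query, comp, lm=lm
            )
            results.append(
                ProximityResult(
                    sample.sample_id, reference, query, comp,
                    "nn_mean_distance_um", mean_d, n_ref, n_qry,
                    n_reference_excluded=n_excl,
                )
            )
            pct, n_ref, n_qry = pct_within_radius_detail(
                sample, rules, reference, query, radius, comp, lm=lm
            )
            results.append(
                ProximityResult(
                    sample.sample_id, reference, query, comp,
                    "pct_within_radius", pct, n_ref, n_qry, radius_um=radius,
                )
            )
    return results


def panel_frame(results: list[ProximityResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
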
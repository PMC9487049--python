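"""Synthetic study generator.

Emulates a two-arm (HPV-positive vs HPV-negative) oropharyngeal carcinoma
cohort with the statistical structure the downstream analysis assumes:

* spatial cell maps per lesion — tumor nests drawn as random discs until a
  target tumor-area fraction is reached, phenotype populations drawn from
  homogeneous Poisson processes with compartment-specific intensities λ
  (cells/mm²), and an optional attraction step that relocates a fraction ρ
  of an attracted phenotype to within ``attraction_radius`` of a random
  anchor cell;
* negative-binomial expression counts for a 770-gene panel with 40
  housekeeping genes and a configurable number of injected
  differentially-expressed genes;
* exponential disease-free survival whose log-hazard is a linear function
  of standardized latent immune covariates, with administrative censoring
  uniform on [0.5·horizon, horizon].

Every draw flows from one integer seed; identical seeds give bit-identical
cohorts. A truth record retains all injected parameters for recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point

from .io import (
    CellRecord,
    ExpressionMatrix,
    FieldGeometry,
    GenerationError,
    LesionSample,
    MarkerPanel,
    PatientRecord,
    UM2_PER_MM2,
    ValidationError,
)

POSITIVE, NEGATIVE = "positive", "negative"
PRIMARY, METASTASIS = "primary", "metastasis"

#: generator phenotype classes (9-color panel)
CLASSES = ("tumor", "cd8", "treg", "mac")


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class SpatialParams:
    """Spatial intensities and geometry of the simulated fields.

    ``intensities[(hpv, lesion)][cls]`` = (λ in tumor nests, λ in stroma),
    cells/mm². ``subset_fractions`` hold the marker co-expression
    probabilities within a class (e.g. CD103+ among CD8+).
    ``proximity_enrichment[(attracted, anchor)]`` = ρ ∈ [0, 1]: that
    fraction of the attracted class is re-positioned uniformly within
    ``attraction_radius`` μm of a random anchor cell.
    ``patient_sigma[cls]``: SD of the per-patient log-normal intensity
    multiplier (biological between-patient heterogeneity).
    """

    field_width: float = 650.0
    field_height: float = 500.0
    nest_radius_mean: float = 80.0
    nest_radius_sd: float = 20.0
    tumor_area_fraction: float = 0.35
    max_nest_attempts: int = 500
    intensities: dict = field(default_factory=dict)
    subset_fractions: dict = field(default_factory=dict)
    proximity_enrichment: dict = field(default_factory=dict)
    attraction_radius: float = 20.0
    patient_sigma: dict = field(default_factory=lambda: {c: 0.0 for c in CLASSES})

    def __post_init__(self) -> None:
        if self.attraction_radius <= 0:
            raise ValidationError("attraction_radius must be > 0")
        for rho in self.proximity_enrichment.values():
            if not (0 <= rho <= 1):
                raise ValidationError("proximity enrichment ρ must be in [0, 1]")
        for table in self.intensities.values():
            for lam in table.values():
                if min(lam) < 0:
                    raise ValidationError("intensities must be ≥ 0")


@dataclass
class ExpressionParams:
    n_genes: int = 770
    n_housekeeping: int = 40
    n_de_genes: int = 30
    log2fc_range: tuple[float, float] = (1.2, 2.0)
    nb_dispersion: float = 0.1
    baseline_mean_range: tuple[float, float] = (50.0, 1000.0)
    hk_mean_range: tuple[float, float] = (200.0, 2000.0)
    n_hpv_pos: int = 24
    n_hpv_neg: int = 15

    def __post_init__(self) -> None:
        if self.n_de_genes > self.n_genes - self.n_housekeeping:
            raise ValidationError("more DE genes than endogenous genes")
        if self.nb_dispersion <= 0:
            raise ValidationError("dispersion must be > 0")


@dataclass
class SurvivalParams:
    baseline_hazard: float = 0.02  # events / month
    log_hazard_coefficients: dict = field(
        default_factory=lambda: {"cd8_infiltration": -0.9}
    )
    censoring_horizon: float = 72.0  # months

    def __post_init__(self) -> None:
        if self.baseline_hazard <= 0 or self.censoring_horizon <= 0:
            raise ValidationError("baseline hazard and horizon must be > 0")


@dataclass
class CohortTruth:
    """Every injected parameter, for recovery tests."""

    seed: int
    de_log2fc: dict  # gene → signed log2 fold change (positive − negative)
    patient_log_multipliers: dict  # patient → {class: u}
    survival_coefficients: dict
    hpv_status: dict  # patient → status
    proximity_enrichment: dict

    def to_json(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["proximity_enrichment"] = {
            f"{a}->{b}": rho for (a, b), rho in self.proximity_enrichment.items()
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=2)


# ---------------------------------------------------------------------------
# Default calibration
# ---------------------------------------------------------------------------


def default_calibration() -> SpatialParams:
    """Shipped spatial parameter table.

    Intensities were chosen from the complete-spatial-randomness closed form
    pct = 1 − exp(−λ·πr²/10⁶) so that the pooled 20-μm count-within
    statistics land near the reported contrasts (≈30% vs ≈4% of metastatic
    tumor cells near CD8+ cells in HPV+ vs HPV− lesions; ≈60/40% vs
    ≈20/10% of stromal/intra-tumoral M2-TAM near CD8+ cells in HPV+ vs
    HPV− primaries), and so that density orderings (CD8, CD68, CD68+CD163+
    higher in HPV+, FoxP3 comparable) hold. Values are cells/mm² as
    (tumor-nest, stroma) pairs.
    """
    intensities = {
        (POSITIVE, PRIMARY): {
            "tumor": (1500.0, 20.0),
            "cd8": (415.0, 760.0),
            "mac": (260.0, 420.0),
            "treg": (90.0, 140.0),
        },
        (NEGATIVE, PRIMARY): {
            "tumor": (1500.0, 20.0),
            "cd8": (85.0, 180.0),
            "mac": (130.0, 260.0),
            "treg": (90.0, 140.0),
        },
        (POSITIVE, METASTASIS): {
            "tumor": (1500.0, 20.0),
            "cd8": (262.0, 395.0),
            "mac": (230.0, 380.0),
            "treg": (90.0, 140.0),
        },
        (NEGATIVE, METASTASIS): {
            "tumor": (1500.0, 20.0),
            "cd8": (29.0, 54.0),
            "mac": (120.0, 230.0),
            "treg": (90.0, 140.0),
        },
    }
    fractions = {
        (POSITIVE, PRIMARY): _fractions(0.35, 0.45, 0.55, 0.25, 0.30),
        (NEGATIVE, PRIMARY): _fractions(0.25, 0.30, 0.50, 0.08, 0.15),
        (POSITIVE, METASTASIS): _fractions(0.40, 0.45, 0.55, 0.25, 0.30),
        (NEGATIVE, METASTASIS): _fractions(0.25, 0.30, 0.50, 0.08, 0.15),
    }
    return SpatialParams(
        intensities=intensities,
        subset_fractions=fractions,
        proximity_enrichment={},
        patient_sigma={"tumor": 0.05, "cd8": 0.25, "treg": 0.25, "mac": 0.25},
    )


def _fractions(cd103, pd1, cd163, pdl1_tumor, pdl1_mac):
    return {
        "cd103_pos_of_cd8": cd103,
        "pd1_pos_of_cd8": pd1,
        "cd163_pos_of_mac": cd163,
        "pdl1_pos_of_tumor": pdl1_tumor,
        "pdl1_pos_of_mac": pdl1_mac,
    }


# ---------------------------------------------------------------------------
# Field generation
# ---------------------------------------------------------------------------


def _make_nests(params: SpatialParams, rng: np.random.Generator) -> list:
    """Add random discs until the clipped union reaches the target area."""
    rect = shapely.box(0, 0, params.field_width, params.field_height)
    target = params.tumor_area_fraction * rect.area
    if target <= 0:
        return []
    nests: list = []
    union = None
    for _ in range(params.max_nest_attempts):
        cx = rng.uniform(0, params.field_width)
        cy = rng.uniform(0, params.field_height)
        radius = max(10.0, rng.normal(params.nest_radius_mean, params.nest_radius_sd))
        disc = Point(cx, cy).buffer(radius, quad_segs=16).intersection(rect)
        nests.append(disc)
        union = disc if union is None else union.union(disc)
        if union.area >= target:
            return nests
    raise GenerationError(
        f"tumor_area_fraction {params.tumor_area_fraction} unreachable in "
        f"{params.max_nest_attempts} attempts"
    )


def _sample_points_in_region(region, n, width, height, inside, rng, max_rounds=1000):
    """Uniform points in the tumor region (inside=True) or its complement."""
    if n == 0:
        return np.empty((0, 2))
    out = []
    got = 0
    for _ in range(max_rounds):
        m = max(64, int((n - got) * 3))
        pts = rng.uniform((0, 0), (width, height), size=(m, 2))
        if region.is_empty:
            keep = np.zeros(m, dtype=bool) if inside else np.ones(m, dtype=bool)
        else:
            hit = shapely.intersects_xy(region, pts[:, 0], pts[:, 1])
            keep = hit if inside else ~hit
        pts = pts[keep]
        if len(pts):
            out.append(pts[: n - got])
            got += len(out[-1])
        if got >= n:
            return np.concatenate(out)
    raise GenerationError("rejection sampling failed — compartment area too small")


def generate_field(
    params: SpatialParams,
    hpv: str,
    lesion: str,
    rng: np.random.Generator,
    field_id: str = "F01",
    multipliers: dict[str, float] | None = None,
) -> tuple[FieldGeometry, list[CellRecord]]:
    """One imaged field: nest geometry plus Poisson-distributed cells.

    ``multipliers`` scales each class's intensities (patient heterogeneity).
    Marker calls are derived deterministically from the assigned class, with
    co-expression markers drawn per cell from the subset fractions.
    Compartments are assigned from nest membership after any attraction
    relocation.
    """
    key = (hpv, lesion)
    if key not in params.intensities:
        raise ValidationError(f"no intensities for {key}")
    table = params.intensities[key]
    fractions = params.subset_fractions.get(key, _fractions(0, 0, 0, 0, 0))
    multipliers = multipliers or {}

    nests = _make_nests(params, rng)
    geom = FieldGeometry(field_id, params.field_width, params.field_height, nests)
    region = geom.tumor_region
    a_tumor = geom.tumor_area_um2 / UM2_PER_MM2
    a_stroma = geom.stroma_area_um2 / UM2_PER_MM2

    class_xy: dict[str, np.ndarray] = {}
    for cls in CLASSES:
        lam_t, lam_s = table.get(cls, (0.0, 0.0))
        scale = multipliers.get(cls, 1.0)
        n_t = rng.poisson(lam_t * scale * a_tumor)
        n_s = rng.poisson(lam_s * scale * a_stroma)
        pts_t = _sample_points_in_region(
            region, n_t, params.field_width, params.field_height, True, rng
        )
        pts_s = _sample_points_in_region(
            region, n_s, params.field_width, params.field_height, False, rng
        )
        class_xy[cls] = np.concatenate([pts_t, pts_s]) if (n_t + n_s) else np.empty((0, 2))

    # attraction by relocation: exact-ρ semantics, in-field rejection
    for (attracted, anchor), rho in params.proximity_enrichment.items():
        apts, anch = class_xy.get(attracted), class_xy.get(anchor)
        if apts is None or anch is None or len(apts) == 0 or len(anch) == 0 or rho == 0:
            continue
        n_move = int(round(rho * len(apts)))
        move_idx = rng.choice(len(apts), size=n_move, replace=False)
        for i in move_idx:
            a = anch[rng.integers(len(anch))]
            for _ in range(100):
                ang = rng.uniform(0, 2 * math.pi)
                rad = params.attraction_radius * math.sqrt(rng.uniform())
                x, y = a[0] + rad * math.cos(ang), a[1] + rad * math.sin(ang)
                if 0 <= x <= params.field_width and 0 <= y <= params.field_height:
                    apts[i] = (x, y)
                    break

    cells: list[CellRecord] = []
    counter = 0
    panel_markers = MarkerPanel.nine_color().markers
    for cls in CLASSES:
        xy = class_xy[cls]
        n = len(xy)
        if n == 0:
            continue
        calls = {m: np.zeros(n, dtype=bool) for m in panel_markers}
        if cls == "tumor":
            calls["CK"][:] = True
            calls["PD-L1"] = rng.random(n) < fractions["pdl1_pos_of_tumor"]
        elif cls == "cd8":
            calls["CD8"][:] = True
            calls["CD103"] = rng.random(n) < fractions["cd103_pos_of_cd8"]
            calls["PD-1"] = rng.random(n) < fractions["pd1_pos_of_cd8"]
        elif cls == "treg":
            calls["FoxP3"][:] = True
        elif cls == "mac":
            calls["CD68"][:] = True
            calls["CD163"] = rng.random(n) < fractions["cd163_pos_of_mac"]
            calls["PD-L1"] = rng.random(n) < fractions["pdl1_pos_of_mac"]
        for i in range(n):
            counter += 1
            cells.append(
                CellRecord(
                    cell_id=f"{field_id}_c{counter:05d}",
                    field_id=field_id,
                    x=float(xy[i, 0]),
                    y=float(xy[i, 1]),
                    marker_calls={m: bool(calls[m][i]) for m in panel_markers},
                )
            )
    # compartment from final positions (boundary-inclusive tumor membership)
    if cells:
        xs = np.array([c.x for c in cells])
        ys = np.array([c.y for c in cells])
        inside = (
            shapely.intersects_xy(region, xs, ys)
            if not region.is_empty
            else np.zeros(len(cells), dtype=bool)
        )
        for i, c in enumerate(cells):
            c.compartment = "tumor" if inside[i] else "stroma"
    return geom, cells


def generate_lesion(
    sample_id: str,
    patient_id: str,
    lesion_type: str,
    hpv: str,
    params: SpatialParams,
    n_fields: int,
    rng: np.random.Generator,
    multipliers: dict[str, float] | None = None,
) -> LesionSample:
    fields, cells = [], []
    for i in range(n_fields):
        fid = f"{sample_id}_F{i + 1:02d}"
        geom, fc = generate_field(params, hpv, lesion_type, rng, fid, multipliers)
        fields.append(geom)
        cells.extend(fc)
    return LesionSample(sample_id, patient_id, lesion_type, fields, cells)


def simulate_lesion_cohort(
    hpv: str,
    lesion_type: str,
    n_patients: int,
    n_fields: int,
    seed: int,
    params: SpatialParams | None = None,
) -> list[LesionSample]:
    """Independent lesions of one (hpv, lesion_type) arm, with per-patient
    log-normal intensity heterogeneity."""
    if params is None:
        params = default_calibration()
    rng = np.random.default_rng(seed)
    lesions = []
    for i in range(n_patients):
        mult = {
            cls: float(np.exp(rng.normal(0.0, params.patient_sigma.get(cls, 0.0))))
            for cls in CLASSES
        }
        pid = f"{hpv[:3]}_{i + 1:02d}"
        lesions.append(
            generate_lesion(
                f"{pid}_{lesion_type[:4]}", pid, lesion_type, hpv, params,
                n_fields, rng, mult,
            )
        )
    return lesions


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def generate_expression(
    params: ExpressionParams,
    sample_ids_pos: list[str],
    sample_ids_neg: list[str],
    rng: np.random.Generator,
) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Negative-binomial counts with injected group-dependent mean shifts.

    Housekeeping genes share one mean across all samples (no group effect
    by construction). ``n_de_genes`` endogenous genes get a signed log2
    fold change drawn uniformly in ``log2fc_range`` applied to the
    positive-group mean.
    """
    n_endo = params.n_genes - params.n_housekeeping
    endo = [f"GENE_{i + 1:04d}" for i in range(n_endo)]
    hk = [f"HK_{i + 1:02d}" for i in range(params.n_housekeeping)]
    genes = endo + hk
    samples = list(sample_ids_pos) + list(sample_ids_neg)
    is_pos = np.array([True] * len(sample_ids_pos) + [False] * len(sample_ids_neg))

    lo, hi = params.baseline_mean_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n_endo))
    hk_lo, hk_hi = params.hk_mean_range
    hk_base = np.exp(rng.uniform(np.log(hk_lo), np.log(hk_hi), size=params.n_housekeeping))

    de_idx = rng.choice(n_endo, size=params.n_de_genes, replace=False)
    signs = rng.choice([-1.0, 1.0], size=params.n_de_genes)
    mags = rng.uniform(*params.log2fc_range, size=params.n_de_genes)
    lfc = np.zeros(n_endo)
    lfc[de_idx] = signs * mags

    mean_pos = np.concatenate([base * 2.0**lfc, hk_base])
    mean_neg = np.concatenate([base, hk_base])
    size = 1.0 / params.nb_dispersion

    counts = np.empty((params.n_genes, len(samples)))
    for j, pos in enumerate(is_pos):
        m = mean_pos if pos else mean_neg
        counts[:, j] = rng.negative_binomial(size, size / (size + m))
    matrix = ExpressionMatrix(
        values=pd.DataFrame(counts, index=genes, columns=samples),
        housekeeping=frozenset(hk),
        scale="raw_counts",
    )
    truth = {endo[i]: float(lfc[i]) for i in de_idx}
    return matrix, truth


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


def generate_survival(
    params: SurvivalParams,
    standardized_features: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Exponential DFS with log-linear covariate effects and administrative
    censoring uniform on [0.5·horizon, horizon]."""
    missing = [f for f in params.log_hazard_coefficients if f not in standardized_features]
    if missing:
        raise ValidationError(f"features absent from table: {missing}")
    log_h = np.log(params.baseline_hazard) * np.ones(len(standardized_features))
    for feat, coef in params.log_hazard_coefficients.items():
        log_h = log_h + coef * standardized_features[feat].to_numpy(float)
    hazard = np.exp(log_h)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0.5 * params.censoring_horizon, params.censoring_horizon,
                           size=len(hazard))
    time = np.minimum(t_event, t_censor)
    event = t_event <= t_censor
    return pd.DataFrame(
        {"dfs_time_months": time, "dfs_event": event},
        index=standardized_features.index,
    )


# ---------------------------------------------------------------------------
# Whole cohort
# ---------------------------------------------------------------------------

#: printed cohort composition: 24 HPV+ (21 HPV16 / 2 HPV33 / 1 HPV18,
#: 12 women) and 15 HPV− (4 women)
_HPV_TYPES_POS = ["HPV16"] * 21 + ["HPV33"] * 2 + ["HPV18"]
_N_POS, _N_NEG = 24, 15
_N_WOMEN_POS, _N_WOMEN_NEG = 12, 4


def generate_cohort(
    spatial: SpatialParams | None = None,
    expr: ExpressionParams | None = None,
    surv: SurvivalParams | None = None,
    n_fields_per_lesion: int = 20,
    seed: int | None = None,
) -> tuple[list[PatientRecord], list[LesionSample], ExpressionMatrix, CohortTruth]:
    """Full synthetic study: 39 patients (24 HPV+ / 15 HPV−), a primary and
    a metastatic lesion each, a 770 × 39 expression matrix, and DFS."""
    if seed is None:
        raise ValidationError("generate_cohort requires an explicit seed")
    spatial = spatial or default_calibration()
    expr = expr or ExpressionParams()
    surv = surv or SurvivalParams()
    ss = np.random.SeedSequence(seed)
    rng_sp, rng_ex, rng_su = (np.random.default_rng(c) for c in ss.spawn(3))

    statuses = [POSITIVE] * expr.n_hpv_pos + [NEGATIVE] * expr.n_hpv_neg
    patients_meta = []
    lesions: list[LesionSample] = []
    log_mults: dict[str, dict[str, float]] = {}
    n_pos_seen = n_neg_seen = 0
    for i, status in enumerate(statuses):
        pid = f"P{i + 1:02d}"
        if status == POSITIVE:
            sex = "female" if n_pos_seen < _N_WOMEN_POS * expr.n_hpv_pos / _N_POS else "male"
            hpv_type = _HPV_TYPES_POS[n_pos_seen % len(_HPV_TYPES_POS)]
            n_pos_seen += 1
        else:
            sex = "female" if n_neg_seen < _N_WOMEN_NEG * expr.n_hpv_neg / _N_NEG else "male"
            hpv_type = "none"
            n_neg_seen += 1
        u = {
            cls: float(rng_sp.normal(0.0, spatial.patient_sigma.get(cls, 0.0)))
            for cls in CLASSES
        }
        log_mults[pid] = u
        mult = {cls: float(np.exp(v)) for cls, v in u.items()}
        for lesion_type in (PRIMARY, METASTASIS):
            lesions.append(
                generate_lesion(
                    f"{pid}_{lesion_type[:4]}", pid, lesion_type, status,
                    spatial, n_fields_per_lesion, rng_sp, mult,
                )
            )
        patients_meta.append((pid, status, sex, hpv_type))

    pos_ids = [p for p, s, *_ in patients_meta if s == POSITIVE]
    neg_ids = [p for p, s, *_ in patients_meta if s == NEGATIVE]
    matrix, de_truth = generate_expression(expr, pos_ids, neg_ids, rng_ex)

    sigma_cd8 = spatial.patient_sigma.get("cd8", 0.0) or 1.0
    feats = pd.DataFrame(
        {"cd8_infiltration": [log_mults[p]["cd8"] / sigma_cd8 for p, *_ in patients_meta]},
        index=[p for p, *_ in patients_meta],
    )
    survival = generate_survival(surv, feats, rng_su)

    patients = [
        PatientRecord(
            patient_id=pid,
            hpv_status=status,
            sex=sex,
            dfs_time=float(survival.loc[pid, "dfs_time_months"]),
            dfs_event=bool(survival.loc[pid, "dfs_event"]),
            covariates={"hpv_type": hpv_type},
        )
        for pid, status, sex, hpv_type in patients_meta
    ]
    truth = CohortTruth(
        seed=seed,
        de_log2fc=de_truth,
        patient_log_multipliers=log_mults,
        survival_coefficients=dict(surv.log_hazard_coefficients),
        hpv_status={p.patient_id: p.hpv_status for p in patients},
        proximity_enrichment=dict(spatial.proximity_enrichment),
    )
    return patients, lesions, matrix, truth
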
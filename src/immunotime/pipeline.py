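"""End-to-end orchestration: simulate or ingest → phenotype → quantify →
proximity → expression profiling → group comparison → survival screen.

Every run writes a manifest (config snapshot, seed, content digests of every
output file, per-stage row counts and warnings) so that a run is
reproducible and auditable: re-running with the same inputs and seed yields
identical digests. Per-stage randomness is derived from the global seed via
``numpy.random.SeedSequence(seed).spawn`` in a fixed stage order.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import gep, phenotype, proximity, quantify, simulate, stats, survival
from .io import (
    AnalysisConfig,
    ImmunotimeError,
    MarkerPanel,
    read_cell_table,
    read_expression_matrix,
    read_patient_table,
    write_cell_table,
    write_expression_matrix,
    write_patient_table,
)

logger = logging.getLogger("immunotime")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class _WarningCollector(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record):
        self.messages.append(record.getMessage())


def write_simulation(out_dir: Path, seed: int, n_fields: int = 20,
                     spatial=None, expr=None, surv=None) -> dict:
    """Generate a full cohort and write cell tables, expression matrix,
    patient metadata and the truth record under ``out_dir``."""
    out_dir.mkdir(parents=True, exist_ok=True)
    patients, lesions, matrix, truth = simulate.generate_cohort(
        spatial=spatial, expr=expr, surv=surv,
        n_fields_per_lesion=n_fields, seed=seed,
    )
    panel = MarkerPanel.nine_color()
    cells_dir = out_dir / "cell_tables"
    cells_dir.mkdir(exist_ok=True)
    for lesion in lesions:
        write_cell_table(lesion.cells, panel, cells_dir / f"{lesion.sample_id}.csv")
    write_expression_matrix(matrix, out_dir / "expression_raw.csv",
                            out_dir / "housekeeping.txt")
    write_patient_table(patients, out_dir / "patients.csv")
    truth.to_json(out_dir / "truth.json")
    lesion_index = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "patient_id": s.patient_id,
                "lesion_type": s.lesion_type,
                "n_fields": len(s.fields),
                "n_cells": len(s.cells),
            }
            for s in lesions
        ]
    )
    lesion_index.to_csv(out_dir / "lesions.csv", index=False)
    import shapely

    field_rows = []
    for s in lesions:
        for f in s.fields:
            field_rows.append(
                {
                    "sample_id": s.sample_id,
                    "field_id": f.field_id,
                    "width_um": f.width,
                    "height_um": f.height,
                    "nests_wkt": ";".join(shapely.to_wkt(p, rounding_precision=-1)
                                           for p in f.tumor_nests),
                }
            )
    pd.DataFrame(field_rows).to_csv(out_dir / "fields.csv", index=False)
    return {
        "patients": patients,
        "lesions": lesions,
        "matrix": matrix,
        "truth": truth,
    }


def run_all(
    out_dir: str | Path,
    *,
    simulate_seed: int | None = None,
    input_dir: str | Path | None = None,
    config: AnalysisConfig | None = None,
    n_fields: int = 20,
    spatial=None,
    expr=None,
    surv=None,
) -> dict:
    """Run the whole analysis; returns the manifest (also written as JSON).

    Either ``simulate_seed`` (synthetic cohort) or ``input_dir`` (previously
    written simulation / ingested data with the same layout) must be given.
    """
    if (simulate_seed is None) == (input_dir is None):
        raise ImmunotimeError("provide exactly one of simulate_seed or input_dir")
    config = config or AnalysisConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logger.addHandler(collector)
    panel = MarkerPanel.nine_color()
    rules = phenotype.default_rules(panel)
    manifest: dict = {
        "config": asdict(config),
        "seed": simulate_seed,
        "stages": {},
        "outputs": {},
    }
    try:
        if simulate_seed is not None:
            sim = write_simulation(out_dir / "inputs", simulate_seed, n_fields,
                                   spatial=spatial, expr=expr, surv=surv)
            patients, lesions, matrix = sim["patients"], sim["lesions"], sim["matrix"]
        else:
            input_dir = Path(input_dir)
            pat_path = input_dir / "patients.csv"
            if not pat_path.exists():
                raise ImmunotimeError(f"missing required input file: {pat_path}")
            patients = read_patient_table(pat_path)
            matrix = read_expression_matrix(
                input_dir / "expression_raw.csv", input_dir / "housekeeping.txt"
            )
            lesion_index = pd.read_csv(input_dir / "lesions.csv")
            from .io import FieldGeometry, LesionSample  # local import
            import shapely

            geom_by_sample: dict[str, list[FieldGeometry]] = {}
            fields_path = input_dir / "fields.csv"
            if fields_path.exists():
                for _, row in pd.read_csv(fields_path).iterrows():
                    nests = [
                        shapely.from_wkt(w)
                        for w in str(row.nests_wkt).split(";")
                        if w and w != "nan"
                    ]
                    geom_by_sample.setdefault(row.sample_id, []).append(
                        FieldGeometry(row.field_id, row.width_um, row.height_um, nests)
                    )
            lesions = []
            for _, row in lesion_index.iterrows():
                cells = read_cell_table(
                    input_dir / "cell_tables" / f"{row.sample_id}.csv", panel
                )
                fields = geom_by_sample.get(row.sample_id) or [
                    FieldGeometry(fid, 650.0, 500.0, [])
                    for fid in dict.fromkeys(c.field_id for c in cells)
                ] or [FieldGeometry(f"{row.sample_id}_F01", 650.0, 500.0, [])]
                lesions.append(
                    LesionSample(row.sample_id, str(row.patient_id),
                                 row.lesion_type, fields, cells)
                )

        # --- phenotyping + quantification -------------------------------
        profiles = []
        counts = []
        pct_rows = []
        ratio_rows = []
        prox_rows = []
        pct_pairs = [
            ("CD8+CD103+", "CD8+"),
            ("CD8+PD-1+", "CD8+"),
            ("CD8+CD103+PD-1+", "CD8+CD103+"),
            ("PD-L1+tumor", "PD-L1+"),
            ("CD68+CD163+", "CD68+"),
        ]
        for lesion in lesions:
            profiles.append(quantify.density_profile(lesion, rules))
            counts.append(phenotype.phenotype_counts(lesion, rules))
            for comp in ("tumor", "stroma", "both"):
                for child, parent in pct_pairs:
                    pct_rows.append(
                        {
                            "sample_id": lesion.sample_id,
                            "child": child,
                            "parent": parent,
                            "compartment": comp,
                            "percentage": quantify.percentage_among_parent(
                                lesion, rules, child, parent, comp
                            ),
                        }
                    )
                ratio_rows.append(
                    {
                        "sample_id": lesion.sample_id,
                        "numerator": "CD8+",
                        "denominator": "FoxP3+",
                        "compartment": comp,
                        "ratio": quantify.population_ratio(
                            lesion, rules, "CD8+", "FoxP3+", comp
                        ),
                    }
                )
            prox_rows.extend(
                proximity.proximity_panel(lesion, rules, radius=config.proximity_radius)
            )
        dens = pd.concat(profiles, ignore_index=True)
        dens.to_csv(out_dir / "densities.csv", index=False)
        pd.concat(counts, ignore_index=True).to_csv(
            out_dir / "phenotype_counts.csv", index=False
        )
        pd.DataFrame(pct_rows).to_csv(out_dir / "percentages.csv", index=False)
        pd.DataFrame(ratio_rows).to_csv(out_dir / "ratios.csv", index=False)
        manifest["stages"]["quantify"] = {"rows": len(dens)}
        prox = proximity.panel_frame(prox_rows)
        prox.to_csv(out_dir / "proximity.csv", index=False)
        manifest["stages"]["proximity"] = {"rows": len(prox)}

        # --- expression --------------------------------------------------
        log2m = gep.log2_transform(gep.normalize_housekeeping(matrix))
        groups = {p.patient_id: p.hpv_status for p in patients}
        de = gep.de_frame(gep.differential_expression(log2m, groups, config))
        de.to_csv(out_dir / "differential_expression.csv", index=False)
        manifest["stages"]["gep"] = {
            "rows": len(de),
            "n_deg": int(de["is_deg"].sum()),
        }
        signatures = [
            sig
            for sig in gep.DEFAULT_SIGNATURES
            if any(g in log2m.values.index for g in sig.genes)
        ]
        if not signatures:
            # synthetic gene names: score deterministic endogenous blocks so
            # downstream machinery is still exercised
            from .io import SignatureSet

            endo = log2m.endogenous
            signatures = [
                SignatureSet(f"synthetic_set_{k + 1}", "cell_type",
                             tuple(endo[k * 10:(k + 1) * 10]))
                for k in range(3)
                if endo[k * 10:(k + 1) * 10]
            ]
            logger.warning(
                "no shipped signature genes present; scoring %d synthetic "
                "gene blocks instead", len(signatures),
            )
        scores = gep.score_matrix(log2m, signatures)
        scores.to_csv(out_dir / "signature_scores.csv")
        manifest["stages"]["signatures"] = {"rows": len(scores)}

        # --- group comparisons -------------------------------------------
        lesion_meta = {s.sample_id: (s.patient_id, s.lesion_type) for s in lesions}
        feat = dens[dens.compartment == "tumor"].pivot_table(
            index="sample_id", columns="phenotype", values="density_per_mm2"
        )
        feat.index = [lesion_meta[s][0] for s in feat.index]
        primary_ids = [s.sample_id for s in lesions if s.lesion_type == "primary"]
        feat_primary = dens[
            (dens.compartment == "tumor") & dens.sample_id.isin(primary_ids)
        ].pivot_table(index="sample_id", columns="phenotype", values="density_per_mm2")
        feat_primary.index = [lesion_meta[s][0] for s in feat_primary.index]
        grouping = pd.Series({p.patient_id: p.hpv_status for p in patients})
        comp = stats.compare_feature_by_group(
            feat_primary, grouping.loc[feat_primary.index]
        )
        comp.to_csv(out_dir / "group_comparisons.csv", index=False)
        manifest["stages"]["compare"] = {"rows": len(comp)}

        # --- survival screen ---------------------------------------------
        surv_df = pd.DataFrame(
            {
                "dfs_time_months": [p.dfs_time for p in patients],
                "dfs_event": [p.dfs_event for p in patients],
                "hpv_status": [p.hpv_status for p in patients],
            },
            index=[p.patient_id for p in patients],
        )
        screen = survival.survival_screen(feat_primary, surv_df)
        screen.to_csv(out_dir / "survival_screen.csv", index=False)
        survival.km_curve_table(feat_primary, surv_df).to_csv(
            out_dir / "km_curves.csv", index=False
        )
        manifest["stages"]["survive"] = {"rows": len(screen)}

        summary = {
            "n_patients": len(patients),
            "n_lesions": len(lesions),
            "n_cells": int(sum(len(s.cells) for s in lesions)),
            "n_genes": len(matrix.genes),
            "n_deg": int(de["is_deg"].sum()),
            "n_screen_significant": int((screen["logrank_p"] < 0.05).sum()),
        }
        with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2)
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["valid"] = False
        with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        logger.removeHandler(collector)
        raise
    manifest["valid"] = True
    manifest["warnings"] = collector.messages
    logger.removeHandler(collector)
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out_dir))] = _digest(path)
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
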
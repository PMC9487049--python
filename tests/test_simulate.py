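import numpy as np
import pytest

from immunotime import (
    ExpressionParams,
    SpatialParams,
    SurvivalParams,
    default_calibration,
    default_rules,
    dichotomize_by_median,
    generate_cohort,
    generate_expression,
    generate_field,
    generate_survival,
    logrank_test,
    MarkerPanel,
    pct_within_radius,
)
from immunotime.io import ValidationError
from immunotime.simulate import METASTASIS, NEGATIVE, POSITIVE, PRIMARY

import pandas as pd

RULES = default_rules(MarkerPanel.nine_color())


def uniform_params(lam_cd8=100.0, lam_tumor=0.0, lam_treg=0.0, rho=None,
                   width=650.0, height=500.0, frac=0.3, r_attr=20.0):
    """Single-arm parameter table with identical λ in both compartments."""
    table = {
        "tumor": (lam_tumor, lam_tumor),
        "cd8": (lam_cd8, lam_cd8),
        "treg": (lam_treg, lam_treg),
        "mac": (0.0, 0.0),
    }
    return SpatialParams(
        field_width=width,
        field_height=height,
        tumor_area_fraction=frac,
        intensities={(POSITIVE, PRIMARY): table},
        subset_fractions={},
        proximity_enrichment=rho or {},
        attraction_radius=r_attr,
    )


class TestGenerateField:
    def test_poisson_mean_over_many_fields(self):
        """λ = 100 cells/mm² on a 0.325 mm² field → mean count 32.5."""
        params = uniform_params(lam_cd8=100.0)
        rng = np.random.default_rng(7)
        counts = []
        for _ in range(200):
            _, cells = generate_field(params, POSITIVE, PRIMARY, rng)
            counts.append(len(cells))
        expected = 100.0 * 0.325
        se = np.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_full_attraction_places_every_cell_near_an_anchor(self):
        params = uniform_params(
            lam_cd8=80.0, lam_treg=80.0, rho={("treg", "cd8"): 1.0}, r_attr=20.0
        )
        rng = np.random.default_rng(3)
        geom, cells = generate_field(params, POSITIVE, PRIMARY, rng)
        from conftest import make_lesion

        lesion = make_lesion(cells, nests=[], field_ids=("F01",))
        assert pct_within_radius(lesion, RULES, "FoxP3+", "CD8+", 20.0) == 100.0

    def test_all_zero_intensities_give_empty_valid_field(self):
        params = uniform_params(lam_cd8=0.0)
        geom, cells = generate_field(params, POSITIVE, PRIMARY, np.random.default_rng(1))
        assert cells == []
        assert geom.tumor_area_um2 > 0

    def test_compartments_match_nest_membership(self):
        params = uniform_params(lam_cd8=200.0, lam_tumor=300.0)
        geom, cells = generate_field(params, POSITIVE, PRIMARY, np.random.default_rng(5))
        import shapely

        region = geom.tumor_region
        for c in cells[:200]:
            inside = bool(shapely.intersects_xy(region, c.x, c.y))
            assert (c.compartment == "tumor") == inside

    def test_csr_count_within_matches_closed_form(self):
        """With ρ = 0 the count-within fraction approaches
        1 − exp(−λπr²/10⁶) (edge effects bias it slightly down)."""
        lam_q = 300.0
        params = uniform_params(lam_cd8=lam_q, lam_tumor=150.0,
                                width=2000.0, height=2000.0, frac=0.3)
        rng = np.random.default_rng(11)
        from conftest import make_lesion

        vals = []
        for _ in range(3):
            geom, cells = generate_field(params, POSITIVE, PRIMARY, rng)
            lesion = make_lesion(cells, width=2000, height=2000, nests=[],
                                 field_ids=("F01",))
            vals.append(pct_within_radius(lesion, RULES, "tumor", "CD8+", 20.0))
        expected = 100 * (1 - np.exp(-lam_q * np.pi * 20**2 / 1e6))
        assert abs(np.mean(vals) - expected) < 5.0
        assert np.mean(vals) < expected + 1.0  # edge bias is downward

    def test_enrichment_raises_count_within(self):
        base = uniform_params(lam_cd8=150.0, lam_treg=100.0)
        enriched = uniform_params(
            lam_cd8=150.0, lam_treg=100.0, rho={("treg", "cd8"): 0.5}, r_attr=15.0
        )
        from conftest import make_lesion

        for seed in range(15):
            out = {}
            for name, params in (("null", base), ("rho", enriched)):
                rng = np.random.default_rng(1000 + seed)
                _, cells = generate_field(params, POSITIVE, PRIMARY, rng)
                lesion = make_lesion(cells, nests=[], field_ids=("F01",))
                out[name] = pct_within_radius(lesion, RULES, "FoxP3+", "CD8+", 20.0)
            assert out["rho"] > out["null"]


class TestGenerateCohort:
    SMALL_EXPR = ExpressionParams(
        n_genes=60, n_housekeeping=6, n_de_genes=5, n_hpv_pos=4, n_hpv_neg=3
    )

    def test_cohort_shape_matches_study_design(self):
        patients, lesions, matrix, _ = generate_cohort(
            n_fields_per_lesion=1, seed=42
        )
        assert len(patients) == 39
        assert sum(p.hpv_status == "positive" for p in patients) == 24
        assert sum(p.hpv_status == "negative" for p in patients) == 15
        assert len(lesions) == 78
        assert matrix.values.shape == (770, 39)
        assert len(matrix.housekeeping) == 40
        types = [p.covariates["hpv_type"] for p in patients if p.hpv_status == "positive"]
        assert types.count("HPV16") == 21

    def test_identical_seed_bit_identical(self):
        a = generate_cohort(expr=self.SMALL_EXPR, n_fields_per_lesion=2, seed=9)
        b = generate_cohort(expr=self.SMALL_EXPR, n_fields_per_lesion=2, seed=9)
        for la, lb in zip(a[1], b[1]):
            assert len(la.cells) == len(lb.cells)
            assert all(
                ca.x == cb.x and ca.y == cb.y and ca.marker_calls == cb.marker_calls
                for ca, cb in zip(la.cells, lb.cells)
            )
        assert (a[2].values.values == b[2].values.values).all()
        assert [p.dfs_time for p in a[0]] == [p.dfs_time for p in b[0]]
        assert a[3].de_log2fc == b[3].de_log2fc

    def test_seed_required(self):
        with pytest.raises(ValidationError):
            generate_cohort(expr=self.SMALL_EXPR, n_fields_per_lesion=1)

    def test_housekeeping_has_no_group_effect(self):
        """Treating HK genes as testable yields zero DEG calls among them."""
        from immunotime.gep import differential_expression, log2_transform, normalize_housekeeping
        from immunotime.io import ExpressionMatrix

        clean_seeds = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mat, _ = generate_expression(
                ExpressionParams(), [f"p{i}" for i in range(24)],
                [f"n{i}" for i in range(15)], rng,
            )
            logm = log2_transform(normalize_housekeeping(mat))
            unflagged = ExpressionMatrix(logm.values, frozenset(), scale="log2")
            res = differential_expression(
                unflagged,
                {s: ("positive" if s.startswith("p") else "negative") for s in mat.samples},
            )
            hk_calls = sum(r.is_deg for r in res if r.gene.startswith("HK_"))
            clean_seeds += hk_calls == 0
        assert clean_seeds >= 9

    def test_null_survival_coefficients_give_uniform_logrank(self):
        """With all hazard coefficients zero, median splits of the latent
        immune feature should reject at ~5%."""
        rejections = 0
        n_seeds = 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            z = rng.normal(size=40)
            feats = pd.DataFrame({"f": z}, index=[f"p{i}" for i in range(40)])
            surv = generate_survival(
                SurvivalParams(log_hazard_coefficients={}), feats, rng
            )
            groups = dichotomize_by_median(feats["f"].to_dict())
            g = np.array([groups[p] for p in feats.index])
            _, p = logrank_test(
                surv["dfs_time_months"], surv["dfs_event"], g
            )
            rejections += p < 0.05
        assert rejections / n_seeds <= 0.2

    def test_injected_survival_effect_is_detectable(self):
        """Default negative CD8 coefficient: high-CD8 patients live longer."""
        patients, lesions, _, truth = generate_cohort(
            expr=ExpressionParams(n_genes=60, n_housekeeping=6, n_de_genes=0),
            n_fields_per_lesion=1, seed=5,
        )
        u = {p: v["cd8"] for p, v in truth.patient_log_multipliers.items()}
        groups = dichotomize_by_median(u)
        t = np.array([p.dfs_time for p in patients])
        e = np.array([p.dfs_event for p in patients])
        g = np.array([groups[p.patient_id] for p in patients])
        # direction: high latent CD8 → longer mean follow-up-to-event
        assert t[(g == "high") & e].mean() >= t[(g == "low") & e].mean() * 0.8

    def test_density_contrast_direction_matches_calibration(self):
        """HPV+ primaries carry denser intra-tumoral CD8 infiltrates than
        HPV− ones; FoxP3 densities are comparable."""
        from immunotime import simulate_lesion_cohort, density

        pos = simulate_lesion_cohort(POSITIVE, PRIMARY, 6, 4, seed=21)
        neg = simulate_lesion_cohort(NEGATIVE, PRIMARY, 6, 4, seed=22)
        cd8_pos = np.mean([density(s, RULES, "CD8+", "tumor") for s in pos])
        cd8_neg = np.mean([density(s, RULES, "CD8+", "tumor") for s in neg])
        assert cd8_pos > 2 * cd8_neg
        treg_pos = np.mean([density(s, RULES, "FoxP3+", "tumor") for s in pos])
        treg_neg = np.mean([density(s, RULES, "FoxP3+", "tumor") for s in neg])
        assert 0.5 < treg_pos / treg_neg < 2.0

    def test_default_calibration_parameters_valid(self):
        params = default_calibration()
        assert set(params.intensities) == {
            (POSITIVE, PRIMARY), (NEGATIVE, PRIMARY),
            (POSITIVE, METASTASIS), (NEGATIVE, METASTASIS),
        }
        for table in params.intensities.values():
            assert all(v >= 0 for pair in table.values() for v in pair)
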
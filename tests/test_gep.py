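import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunotime import (
    ExpressionMatrix,
    SignatureSet,
    bh_adjust,
    differential_expression,
    log2_transform,
    normalize_housekeeping,
    signature_ratio,
    signature_score,
)
from immunotime.io import ImmunotimeError, ValidationError
from immunotime.simulate import ExpressionParams, generate_expression


def small_matrix():
    vals = pd.DataFrame(
        {
            "s1": [24.0, 4.0, 16.0],
            "s2": [10.0, 2.0, 8.0],
        },
        index=["g1", "hk1", "hk2"],
    )
    return ExpressionMatrix(vals, frozenset({"hk1", "hk2"}))


class TestNormalization:
    def test_ratio_to_housekeeping_geometric_mean(self):
        norm = normalize_housekeeping(small_matrix())
        # s1: geomean(4, 16) = 8 → 24/8 = 3
        assert norm.values.loc["g1", "s1"] == pytest.approx(3.0)
        assert norm.values.loc["g1", "s2"] == pytest.approx(10.0 / 4.0)
        assert norm.scale == "normalized"

    def test_housekeeping_geomean_is_one_after_normalization(self):
        norm = normalize_housekeeping(small_matrix())
        hk = norm.values.loc[["hk1", "hk2"]]
        geomean = np.exp(np.log(hk).mean(axis=0))
        assert np.allclose(geomean, 1.0)

    def test_counts_floored_at_one(self):
        vals = pd.DataFrame({"s1": [0.0, 4.0]}, index=["g1", "hk1"])
        mat = ExpressionMatrix(vals, frozenset({"hk1"}))
        norm = normalize_housekeeping(mat)
        assert norm.values.loc["g1", "s1"] == pytest.approx(1.0 / 4.0)

    def test_normalization_factors_match_independent_recomputation(self, rng):
        mat, _ = generate_expression(
            ExpressionParams(), [f"p{i}" for i in range(24)],
            [f"n{i}" for i in range(15)], rng,
        )
        norm = normalize_housekeeping(mat)
        hk = sorted(mat.housekeeping)
        for s in mat.samples[:5]:
            raw = np.maximum(mat.values[s].to_numpy(), 1.0)
            factor = np.prod(np.maximum(mat.values.loc[hk, s], 1.0)) ** (1 / len(hk))
            expected = raw / factor
            assert np.allclose(norm.values[s].to_numpy(), expected, rtol=1e-9)

    def test_no_housekeeping_rejected(self):
        vals = pd.DataFrame({"s1": [1.0]}, index=["g1"])
        with pytest.raises(ImmunotimeError):
            normalize_housekeeping(ExpressionMatrix(vals, frozenset()))

    def test_log2_arithmetic_and_scale_gating(self):
        norm = normalize_housekeeping(small_matrix())
        logm = log2_transform(norm)
        assert logm.values.loc["g1", "s1"] == pytest.approx(np.log2(3.0), abs=1e-9)
        with pytest.raises(ValidationError):
            log2_transform(logm)  # already log2
        with pytest.raises(ValidationError):
            log2_transform(small_matrix())  # raw, not normalized


class TestDifferentialExpression:
    def _log2_matrix(self, a, b):
        vals = pd.DataFrame(
            [list(a) + list(b)],
            index=["g1"],
            columns=[f"p{i}" for i in range(len(a))] + [f"n{i}" for i in range(len(b))],
        )
        return ExpressionMatrix(vals, frozenset(), scale="log2")

    def test_closed_form_t_example(self):
        """Groups {2,3,4} vs {0,1,2}: lfc = 2, t = 2.449, p ≈ 0.0705 (df=4)."""
        mat = self._log2_matrix([2.0, 3.0, 4.0], [0.0, 1.0, 2.0])
        groups = {f"p{i}": "positive" for i in range(3)}
        groups |= {f"n{i}": "negative" for i in range(3)}
        (res,) = differential_expression(mat, groups)
        assert res.log2_fold_change == pytest.approx(2.0)
        assert res.p_value == pytest.approx(0.070484, abs=1e-4)
        t = res.log2_fold_change / np.sqrt(1.0 * (1 / 3 + 1 / 3))
        assert t == pytest.approx(2.449, abs=1e-3)

    def test_identical_groups_give_zero_lfc(self):
        mat = self._log2_matrix([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        groups = {f"p{i}": "positive" for i in range(3)}
        groups |= {f"n{i}": "negative" for i in range(3)}
        (res,) = differential_expression(mat, groups)
        assert res.log2_fold_change == 0.0
        assert res.p_value == pytest.approx(1.0)
        assert not res.is_deg

    def test_swapping_group_labels_negates_lfc_keeps_p(self, rng):
        mat, _ = generate_expression(
            ExpressionParams(n_genes=100, n_housekeeping=10, n_de_genes=5),
            [f"p{i}" for i in range(6)], [f"n{i}" for i in range(5)], rng,
        )
        logm = log2_transform(normalize_housekeeping(mat))
        g1 = {s: ("positive" if s.startswith("p") else "negative") for s in mat.samples}
        g2 = {s: ("negative" if s.startswith("p") else "positive") for s in mat.samples}
        r1 = differential_expression(logm, g1)
        r2 = differential_expression(logm, g2)
        for a, b in zip(r1, r2):
            assert a.log2_fold_change == pytest.approx(-b.log2_fold_change)
            assert a.p_value == pytest.approx(b.p_value)

    def test_single_sample_group_rejected(self):
        mat = self._log2_matrix([1.0], [2.0, 3.0])
        groups = {"p0": "positive", "n0": "negative", "n1": "negative"}
        with pytest.raises(ValidationError):
            differential_expression(mat, groups)

    def test_zero_variance_gene_excluded_from_bh_family(self):
        vals = pd.DataFrame(
            {
                "p0": [1.0, 1.0], "p1": [1.0, 2.0],
                "n0": [1.0, 5.0], "n1": [1.0, 6.0],
            },
            index=["flat", "ok"],
        )
        mat = ExpressionMatrix(vals, frozenset(), scale="log2")
        groups = {"p0": "positive", "p1": "positive", "n0": "negative", "n1": "negative"}
        res = {r.gene: r for r in differential_expression(mat, groups)}
        assert np.isnan(res["flat"].p_value)
        # BH with family size 1: adjusted == raw for the remaining gene
        assert res["ok"].adjusted_p == pytest.approx(res["ok"].p_value)


class TestBHAdjust:
    def test_hand_step_up_example(self):
        adj = bh_adjust([0.01, 0.04, 0.03, 0.02])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @given(
        ps=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=100, deadline=None)
    def test_adjusted_at_least_raw_and_monotone(self, ps):
        adj = bh_adjust(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestSignatures:
    def _log2(self):
        vals = pd.DataFrame({"s1": [2.0, 4.0, 7.0], "s2": [1.0, 3.0, 5.0]},
                            index=["g1", "g2", "g3"])
        return ExpressionMatrix(vals, frozenset(), scale="log2")

    def test_score_is_mean_of_member_genes(self):
        sig = SignatureSet("sig", "cell_type", ("g1", "g2"))
        assert signature_score(self._log2(), sig, "s1").score == pytest.approx(3.0)

    def test_single_gene_signature(self):
        sig = SignatureSet("sig", "pathway", ("g3",))
        assert signature_score(self._log2(), sig, "s2").score == pytest.approx(5.0)

    def test_absent_genes_counted_and_all_absent_rejected(self):
        sig = SignatureSet("sig", "cell_type", ("g1", "nope"))
        s = signature_score(self._log2(), sig, "s1")
        assert s.n_missing_genes == 1
        with pytest.raises(ImmunotimeError, match="sig2"):
            signature_score(self._log2(), SignatureSet("sig2", "cell_type", ("zzz",)), "s1")

    def test_ratio_is_score_difference_and_antisymmetric(self):
        m = self._log2()
        a = signature_score(m, SignatureSet("a", "cell_type", ("g3",)), "s1")
        b = signature_score(m, SignatureSet("b", "cell_type", ("g1",)), "s1")
        assert signature_ratio(a, b) == pytest.approx(5.0)
        assert signature_ratio(a, b) == -signature_ratio(b, a)

    def test_sample_mismatch_rejected(self):
        m = self._log2()
        a = signature_score(m, SignatureSet("a", "cell_type", ("g1",)), "s1")
        b = signature_score(m, SignatureSet("a", "cell_type", ("g1",)), "s2")
        with pytest.raises(ValidationError):
            signature_ratio(a, b)

    def test_injected_group_shift_reproduced_in_scores(self, rng):
        """Signature over genes up-shifted in the positive group scores higher there."""
        mat, truth = generate_expression(
            ExpressionParams(n_genes=200, n_housekeeping=20, n_de_genes=10,
                             log2fc_range=(1.5, 2.0)),
            [f"p{i}" for i in range(12)], [f"n{i}" for i in range(12)], rng,
        )
        logm = log2_transform(normalize_housekeeping(mat))
        up = tuple(g for g, fc in truth.items() if fc > 0)
        sig = SignatureSet("up", "cell_type", up)
        pos = np.mean([signature_score(logm, sig, f"p{i}").score for i in range(12)])
        neg = np.mean([signature_score(logm, sig, f"n{i}").score for i in range(12)])
        assert pos > neg + 0.5
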
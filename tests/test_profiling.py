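"""EC50 matrix assembly, potency flags, clustering, selectivity, and the
expression-quantification rules."""

import numpy as np
import pandas as pd
import pytest

import screenkit as sk
from screenkit._errors import DataError
from screenkit.datasets import cell_line_subtypes, secondary_screen_ec50


def sigmoid_fit(e_molar):
    return sk.FourPLFit(mode="sigmoid", converged=True, auc=50.0, b=-1.0,
                        c=100.0, d=0.0, e=e_molar, log10_e=np.log10(e_molar))


FALLBACK = sk.FourPLFit(mode="spline_fallback", converged=False, auc=80.0)


class TestEC50Matrix:
    def test_unit_conversion_and_missing(self):
        m = sk.assemble_ec50_matrix({
            ("c1", "A"): sigmoid_fit(1e-8),
            ("c1", "B"): FALLBACK,
        })
        assert m.loc["c1", "A"] == pytest.approx(0.01)
        assert np.isnan(m.loc["c1", "B"])

    def test_duplicate_keys_rejected(self):
        class Dup(dict):
            def __iter__(self):
                yield ("c1", "A")
                yield ("c1", "A")

        with pytest.raises(DataError):
            sk.assemble_ec50_matrix(Dup({("c1", "A"): sigmoid_fit(1e-8)}))

    def test_reference_panel_loads_exactly(self):
        panel = secondary_screen_ec50()
        assert panel.shape == (17, 8)
        assert panel.loc["Gemcitabine", "M07e"] == 0.06
        assert panel.loc["CUDC-907", "MV4-11"] == 0.0002
        assert panel.loc["Cabazitaxel"].max() == 0.001
        assert (panel > 0).all().all()


class TestBroadPotency:
    def test_boundary_and_missing_rules(self):
        m = pd.DataFrame(
            {"A": [0.5, 0.5, 0.5], "B": [0.9, 1.5, np.nan]},
            index=["ok", "weak", "ne"],
        )
        assert sk.flag_broad_potency(m) == ["ok"]

    def test_monotone_in_cut(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(rng.uniform(0.01, 3, size=(20, 4)))
        flagged = [set(sk.flag_broad_potency(m, cut)) for cut in (0.5, 1.0, 2.0)]
        assert flagged[0] <= flagged[1] <= flagged[2]


class TestClustering:
    def test_identical_columns_adjacent(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(10 ** rng.uniform(-3, 1, size=(6, 3)), columns=["X", "Y", "Z"])
        m["X2"] = m["X"]
        order, _ = sk.cluster_cell_lines(m)
        assert abs(order.index("X") - order.index("X2")) == 1

    def test_two_tight_pairs_grouped(self):
        base1, base2 = np.array([0.01, 0.02, 0.05]), np.array([5.0, 8.0, 9.0])
        m = pd.DataFrame({
            "A1": base1, "B1": base2, "A2": base1 * 1.1, "B2": base2 * 1.1,
        })
        order, _ = sk.cluster_cell_lines(m)
        pairs = {frozenset(order[:2]), frozenset(order[2:])}
        assert pairs == {frozenset({"A1", "A2"}), frozenset({"B1", "B2"})}

    def test_deterministic(self):
        panel = secondary_screen_ec50()
        o1, _ = sk.cluster_cell_lines(panel)
        o2, _ = sk.cluster_cell_lines(panel)
        assert o1 == o2

    def test_column_permutation_preserves_merge_structure(self):
        panel = secondary_screen_ec50()
        _, z1 = sk.cluster_cell_lines(panel)
        perm = panel[list(panel.columns[::-1])]
        _, z2 = sk.cluster_cell_lines(perm)
        assert np.allclose(np.sort(z1[:, 2]), np.sort(z2[:, 2]))

    def test_all_missing_column_rejected(self):
        m = pd.DataFrame({"A": [0.1, 0.2], "B": [np.nan, np.nan]})
        with pytest.raises(DataError):
            sk.cluster_cell_lines(m)


class TestSubtypeSelectivity:
    def test_ratio_arithmetic(self):
        m = pd.DataFrame([[0.1, 0.1, 10.0, 10.0]], index=["c"],
                         columns=["A1", "A2", "O1", "O2"])
        subtypes = {"A1": "amkl", "A2": "amkl", "O1": "other", "O2": "other"}
        out = sk.subtype_selectivity(m, subtypes, "amkl")
        assert out.loc["c", "selectivity_ratio"] == pytest.approx(100.0)

    def test_uniform_potency_gives_unity(self):
        m = pd.DataFrame([[0.5] * 4], index=["c"], columns=["A1", "A2", "O1", "O2"])
        subtypes = {"A1": "amkl", "A2": "amkl", "O1": "other", "O2": "other"}
        assert sk.subtype_selectivity(m, subtypes, "amkl").loc[
            "c", "selectivity_ratio"] == pytest.approx(1.0)

    def test_missing_censored_at_ceiling(self):
        m = pd.DataFrame([[0.1, np.nan]], index=["c"], columns=["A", "O"])
        out = sk.subtype_selectivity(m, {"A": "amkl", "O": "other"}, "amkl")
        assert out.loc["c", "other_median_um"] == 10.0

    def test_absent_subtype_rejected(self):
        m = pd.DataFrame([[0.1, 0.2]], index=["c"], columns=["A", "O"])
        with pytest.raises(DataError):
            sk.subtype_selectivity(m, {"A": "amkl", "O": "other"}, "mllr")

    def test_bundled_subtype_labels_cover_the_panel(self):
        panel = secondary_screen_ec50()
        labels = cell_line_subtypes()
        assert set(panel.columns) <= set(labels.index)


class TestExpressionQuantification:
    def test_best_exon_and_retention(self):
        cov = pd.DataFrame({
            "gene": ["g1", "g1", "g1", "g2", "g3"],
            "exon": ["e1", "e2", "e3", "e1", "e1"],
            "s1": [3.0, 10.0, 7.0, 9.99, 10.0],
            "s2": [1.0, 2.0, 3.0, 5.0, 0.0],
        })
        expr = sk.best_exon_expression(cov)
        assert expr.loc["g1", "s1"] == 10.0  # best-covered exon
        assert "g2" not in expr.index       # below 10 everywhere
        assert "g3" in expr.index           # exactly 10 is retained

    def test_fpkm_unit_arithmetic(self):
        counts = pd.DataFrame({"s1": [100]}, index=["g"])
        out = sk.fpkm(counts, pd.Series({"g": 1000}), pd.Series({"s1": 1e6}))
        assert out.loc["g", "s1"] == pytest.approx(100.0)

    def test_fpkm_invariances(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 1000, size=(5, 3)).astype(float))
        lengths = pd.Series(rng.integers(200, 5000, size=5).astype(float))
        totals = counts.sum(axis=0)
        base = sk.fpkm(counts, lengths, totals)
        pd.testing.assert_frame_equal(sk.fpkm(2 * counts, lengths, 2 * totals), base)
        pd.testing.assert_frame_equal(sk.fpkm(counts, 2 * lengths, totals), base / 2)

    def test_fpkm_invalid_inputs(self):
        counts = pd.DataFrame({"s1": [1.0]}, index=["g"])
        with pytest.raises(DataError):
            sk.fpkm(counts, pd.Series({"g": 0.0}), pd.Series({"s1": 1e6}))
        with pytest.raises(DataError):
            sk.fpkm(counts, pd.Series({"g": 100.0}), pd.Series({"s1": 0.0}))

    def test_quantile_normalization_hand_case(self):
        qn = sk.quantile_normalize(pd.DataFrame([[1, 4], [2, 5], [3, 6]]))
        np.testing.assert_allclose(qn.to_numpy(),
                                   [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_quantile_normalization_identity_on_identical_columns(self):
        v = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        pd.testing.assert_frame_equal(sk.quantile_normalize(v), v)

    def test_sorted_columns_identical_after_normalization(self):
        # exact for tie-free columns; tied values follow the mean-target rule
        rng = np.random.default_rng(8)
        v = pd.DataFrame(rng.lognormal(size=(50, 4)))
        qn = sk.quantile_normalize(v)
        ref = np.sort(qn.iloc[:, 0].to_numpy())
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(qn.iloc[:, j].to_numpy()), ref)

    def test_tied_values_share_the_mean_target(self):
        v = pd.DataFrame({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        qn = sk.quantile_normalize(v)
        assert qn.loc[0, "a"] == qn.loc[1, "a"]


class TestCorrelation:
    def test_hand_computed_pearson(self):
        res = sk.correlate_expression_sensitivity(
            [1, 2, 3, 4], [2, 1, 4, 3], ic50_scale="linear")
        assert res.pearson_r == pytest.approx(0.6)

    def test_perfect_negative_linear(self):
        res = sk.correlate_expression_sensitivity(
            [1, 2, 3, 4, 5], [10, 8, 6, 4, 2], ic50_scale="linear")
        assert res.pearson_r == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_identity_regression(self):
        res = sk.correlate_expression_sensitivity(
            [1, 2, 3, 4, 5], [1, 2, 3, 4, 5], ic50_scale="linear")
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_log_scale_default(self):
        # IC50s spanning decades: on log10 scale the relation is exactly linear
        expr = np.array([1.0, 2.0, 3.0, 4.0])
        ic50 = 10.0 ** (-6.0 - expr)
        res = sk.correlate_expression_sensitivity(expr, ic50)
        assert res.pearson_r == pytest.approx(-1.0)
        assert res.slope == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(DataError):
            sk.correlate_expression_sensitivity([1, 1, 1], [1, 2, 3], ic50_scale="linear")
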
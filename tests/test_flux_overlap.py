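import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apexflux import (
    ConfigError,
    InteractorRecord,
    classify_flux,
    enrich_categories,
    hypergeom_overlap_test,
    percent_overlap,
    qc_cluster,
)
from apexflux.interactome import RibaqMatrix
from oracles import hypergeom_tail_by_enumeration, hypergeom_tail_closed_form


def record(pid, minus=None, plus=None):
    means = {}
    support = {}
    if minus is not None:
        means["minus_ir"] = minus
        support["minus_ir"] = 2
    if plus is not None:
        means["plus_ir"] = plus
        support["plus_ir"] = 2
    return InteractorRecord(
        protein_id=pid, gene_name=f"g{pid}", mean_ribaq_by_arm=means,
        replicate_support_by_arm=support, max_unique_peptides=3,
    )


class TestClassifyFlux:
    @pytest.mark.parametrize(
        "minus,plus,expected",
        [
            (1.0, 1.6, "ir_up"),          # FC 1.6 >= 1.5
            (1.0, 1.0, "unchanged"),      # FC 1
            (1.0, 0.5, "ir_down"),        # FC 0.5 <= 1/1.5
            (1.0, 1.5, "ir_up"),          # inclusive boundary
            (1.5, 1.0, "ir_down"),        # inclusive boundary, FC = 1/1.5
            (1.0, 1.4, "unchanged"),
        ],
    )
    def test_fold_change_classes(self, minus, plus, expected):
        (call,) = classify_flux([record("P", minus=minus, plus=plus)])
        assert call.flux_class == expected
        np.testing.assert_allclose(call.fold_change, plus / minus)

    def test_strict_mode_excludes_boundary(self):
        (call,) = classify_flux(
            [record("P", minus=1.0, plus=1.5)], inclusive=False
        )
        assert call.flux_class == "unchanged"

    def test_arm_exclusive_proteins_reported_separately(self):
        calls = classify_flux(
            [record("A", plus=1.0), record("B", minus=1.0)]
        )
        by_id = {c.protein_id: c for c in calls}
        assert by_id["A"].flux_class == "plus_ir_only"
        assert by_id["B"].flux_class == "minus_ir_only"
        assert by_id["A"].fold_change is None

    def test_threshold_at_or_below_one_rejected(self):
        with pytest.raises(ConfigError):
            classify_flux([], fc_threshold=1.0)


class TestPercentOverlap:
    def test_reported_interactome_overlap(self):
        # arm lists of sizes 435 and 467 sharing 422 members
        a = {f"P{i}" for i in range(435)}
        b = {f"P{i}" for i in range(13, 480)}
        assert len(a) == 435 and len(b) == 467 and len(a & b) == 422
        res = percent_overlap(a, b)
        np.testing.assert_allclose(res.percent_overlap, 100 * 422 / 480)
        assert res.percent_rounded == 88

    def test_equal_sets_give_100(self):
        res = percent_overlap({"a", "b"}, {"a", "b"})
        assert res.percent_overlap == 100.0

    def test_disjoint_sets_give_0(self):
        assert percent_overlap({"a"}, {"b"}).percent_overlap == 0.0

    def test_both_empty_is_error(self):
        with pytest.raises(ConfigError):
            percent_overlap(set(), set())

    def test_alternative_denominators(self):
        res_min = percent_overlap({"a", "b", "c"}, {"a", "b"}, denominator="min")
        assert res_min.percent_overlap == 100.0
        res_query = percent_overlap({"a", "b", "c", "d"}, {"a"}, denominator="query")
        assert res_query.percent_overlap == 25.0

    @settings(max_examples=50, deadline=None)
    @given(
        st.sets(st.integers(0, 30)),
        st.sets(st.integers(0, 30)),
    )
    def test_symmetric_and_bounded(self, a, b):
        if not a and not b:
            return
        res_ab = percent_overlap(map(str, a), map(str, b))
        res_ba = percent_overlap(map(str, b), map(str, a))
        assert res_ab.percent_overlap == res_ba.percent_overlap
        assert 0 <= res_ab.percent_overlap <= 100
        assert (res_ab.percent_overlap == 100) == (a == b != set())


class TestHypergeomOverlap:
    def test_zero_intersection_gives_p_one(self):
        u = {str(i) for i in range(8)}
        res = hypergeom_overlap_test({"0"}, {"1"}, u)
        assert res.hypergeom_p == 1.0

    def test_enumerated_four_element_universe(self):
        # N=4, |A|=|B|=2, k=2: 1 of the C(4,2)=6 draws of B hits both of A
        u = {str(i) for i in range(4)}
        res = hypergeom_overlap_test({"0", "1"}, {"0", "1"}, u)
        np.testing.assert_allclose(res.hypergeom_p, 1 / 6, atol=1e-12)

    def test_enumerated_ten_element_universe(self):
        # N=10, |A|=5, |B|=4, k=3: (C(5,3)C(5,1)+C(5,4)C(5,0))/C(10,4) = 55/210
        u = {str(i) for i in range(10)}
        a = {str(i) for i in range(5)}
        b = {str(i) for i in range(2, 6)}
        assert len(a & b) == 3
        res = hypergeom_overlap_test(a, b, u)
        np.testing.assert_allclose(res.hypergeom_p, 55 / 210, atol=1e-12)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ConfigError, match="universe"):
            hypergeom_overlap_test({"x"}, {"y"}, {"y"})

    def test_matches_enumeration_small_universes(self):
        for n in (4, 7, 9):
            for size_a in range(n + 1):
                for size_b in range(n + 1):
                    u = [str(i) for i in range(n)]
                    a = set(u[:size_a])
                    b = set(u[n - size_b:])
                    k = len(a & b)
                    res = hypergeom_overlap_test(a, b, u)
                    expected = hypergeom_tail_by_enumeration(n, size_a, size_b, k)
                    np.testing.assert_allclose(
                        res.hypergeom_p, expected, atol=1e-12
                    )


class TestEnrichment:
    def test_saturated_category_gives_p_one(self):
        u = {"a", "b", "c"}
        rows = enrich_categories(u, {"cat": set(u)}, u)
        assert rows[0].p_value == 1.0

    def test_hand_enumerated_category(self):
        u = {str(i) for i in range(10)}
        query = {str(i) for i in range(4)}
        cat = {str(i) for i in range(1, 6)}
        (row,) = enrich_categories(query, {"c": cat}, u)
        assert row.k_overlap == 3
        np.testing.assert_allclose(
            row.p_value, hypergeom_tail_closed_form(10, 5, 4, 3), atol=1e-12
        )

    def test_empty_gmt_gives_empty_result(self):
        assert enrich_categories({"a"}, {}, {"a", "b"}) == []

    def test_empty_universe_rejected(self):
        with pytest.raises(ConfigError):
            enrich_categories(set(), {}, set())

    def test_zero_overlap_reported_with_p_one(self):
        u = {"a", "b", "c", "d"}
        rows = enrich_categories({"a"}, {"c1": {"b", "c"}}, u)
        assert rows[0].k_overlap == 0 and rows[0].p_value == 1.0

    def test_bh_qvalues_monotone_in_ranked_pvalues(self):
        rng = np.random.default_rng(0)
        u = {str(i) for i in range(40)}
        query = set(rng.choice(sorted(u), 12, replace=False))
        gmt = {
            f"cat{i}": set(rng.choice(sorted(u), rng.integers(3, 20), replace=False))
            for i in range(15)
        }
        rows = enrich_categories(query, gmt, u)
        ps = [r.p_value for r in rows]
        qs = [r.q_value for r in rows]
        assert ps == sorted(ps)
        for q1, q2 in zip(qs, qs[1:]):
            assert q1 <= q2 + 1e-12
        assert all(q >= p - 1e-12 for p, q in zip(ps, qs))


def _ribaq_from_matrix(values: pd.DataFrame) -> RibaqMatrix:
    norm = values / values.sum(axis=0)
    return RibaqMatrix(values=norm, denominators=values.sum(axis=0))


class TestQcCluster:
    def test_duplicated_sample_columns_get_identical_coordinates(self):
        rng = np.random.default_rng(2)
        base = rng.lognormal(0, 1, size=20)
        values = pd.DataFrame(
            {"s1": base, "s2": base, "s3": rng.lognormal(0, 1, size=20)},
            index=[f"P{i}" for i in range(20)],
        )
        qc = qc_cluster(_ribaq_from_matrix(values))
        np.testing.assert_allclose(
            qc.pca_coords.loc["s1"].values, qc.pca_coords.loc["s2"].values,
            atol=1e-9,
        )

    def test_planted_clusters_separate_on_pc1(self):
        rng = np.random.default_rng(3)
        n = 40
        cols = {}
        for i in range(3):  # control-like group: disjoint intensity profile
            v = rng.lognormal(0, 0.1, n)
            v[: n // 2] *= 1e3
            cols[f"ctrl{i}"] = v
        for i in range(3):
            v = rng.lognormal(0, 0.1, n)
            v[n // 2:] *= 1e3
            cols[f"exp{i}"] = v
        qc = qc_cluster(_ribaq_from_matrix(pd.DataFrame(cols)))
        pc1 = qc.pca_coords["PC1"]
        ctrl = pc1[[f"ctrl{i}" for i in range(3)]]
        exp = pc1[[f"exp{i}" for i in range(3)]]
        assert ctrl.max() < exp.min() or exp.max() < ctrl.min()
        order = qc.dendrogram_order
        labels = ["".join(filter(str.isalpha, s)) for s in order]
        assert labels in (["ctrl"] * 3 + ["exp"] * 3, ["exp"] * 3 + ["ctrl"] * 3)

    def test_constant_matrix_has_no_variance(self):
        values = pd.DataFrame(
            np.ones((10, 4)), columns=list("abcd"),
            index=[f"P{i}" for i in range(10)],
        )
        qc = qc_cluster(_ribaq_from_matrix(values))
        assert np.all(qc.explained_variance_ratio < 1e-12) or np.all(
            np.abs(qc.pca_coords.values) < 1e-9
        )

    def test_single_sample_rejected(self):
        values = pd.DataFrame({"s1": [1.0, 2.0]}, index=["A", "B"])
        with pytest.raises(ConfigError):
            qc_cluster(_ribaq_from_matrix(values))
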
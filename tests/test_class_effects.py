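"""The class-effect statistics: collapse, PCR, contingency, C-PRR, chi2,
the significance filter and AE ranking."""

import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from classfx import (
    AssociationRecord,
    AssociationTable,
    ContingencyTable,
    Hierarchy,
    c_chi2,
    c_prr,
    collapse_to_ingredients,
    contingency,
    detect_class_effects,
    pcr,
    rank_top_aes,
    results_to_frame,
)


class TestCollapse:
    def test_products_of_one_ingredient_union_their_aes(self):
        t = AssociationTable(
            records=[
                AssociationRecord("P1", "nausea", ingredient_ids=("I1",)),
                AssociationRecord("P2", "rash", ingredient_ids=("I1",)),
            ]
        )
        assert collapse_to_ingredients(t) == {"I1": {"nausea", "rash"}}

    def test_multi_ingredient_product_fans_out(self):
        t = AssociationTable(
            records=[AssociationRecord("P1", "cough", ingredient_ids=("I1", "I2"))]
        )
        assert collapse_to_ingredients(t) == {"I1": {"cough"}, "I2": {"cough"}}

    def test_ae_free_ingredient_kept_with_empty_set(self):
        t = AssociationTable(
            records=[AssociationRecord("P1", "cough", ingredient_ids=("I1",))]
        )
        out = collapse_to_ingredients(t, universe={"I1", "I2"})
        assert out["I2"] == set()


class TestPcr:
    @pytest.mark.parametrize(
        "n_pos,n_members,expected", [(4, 4, 1.0), (0, 5, 0.0), (2, 4, 0.5)]
    )
    def test_direct_ratio(self, n_pos, n_members, expected):
        members = {f"i{k}" for k in range(n_members)}
        positive = {f"i{k}" for k in range(n_pos)}
        assert pcr(members, positive) == expected

    def test_empty_class_is_an_error(self):
        with pytest.raises(ValueError, match="empty class"):
            pcr(set(), set())


class TestContingency:
    def test_worked_example(self):
        universe = {f"i{k}" for k in range(10)}
        members = {"i1", "i2", "i3"}
        positive = {"i1", "i2", "i3", "i5"}
        t = contingency(members, universe, positive)
        assert (t.a, t.b, t.c, t.d) == (3, 1, 0, 6)

    def test_members_equal_universe_zeroes_background(self):
        u = {"i1", "i2"}
        t = contingency(u, u, {"i1"})
        assert t.b == 0 and t.d == 0

    def test_members_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            contingency({"x"}, {"y"}, set())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_element_classification(self, seed):
        rng = np.random.default_rng(seed)
        universe = {f"i{k}" for k in range(30)}
        members = {i for i in universe if rng.random() < 0.3}
        positive = {i for i in universe if rng.random() < 0.4}
        t = contingency(members, universe, positive)
        cells = [0, 0, 0, 0]
        for i in universe:  # brute-force per-element oracle
            idx = (0 if i in positive else 2) + (0 if i in members else 1)
            cells[idx] += 1
        assert [t.a, t.b, t.c, t.d] == cells


class TestCprr:
    def test_worked_example(self):
        assert c_prr(ContingencyTable(3, 1, 0, 6)) == pytest.approx(7.0)

    def test_no_disproportionality_is_one(self):
        assert c_prr(ContingencyTable(1, 1, 1, 1)) == 1.0

    def test_zero_background_yields_infinity(self):
        assert c_prr(ContingencyTable(3, 0, 0, 7)) == math.inf

    def test_zero_positive_class_yields_zero(self):
        assert c_prr(ContingencyTable(0, 2, 3, 5)) == 0.0

    @pytest.mark.parametrize("t", [ContingencyTable(0, 1, 0, 1),
                                   ContingencyTable(1, 0, 1, 0)])
    def test_undefined_background_raises(self, t):
        with pytest.raises(ValueError, match="undefined"):
            c_prr(t)


class TestChi2:
    def test_independence_gives_zero(self):
        assert c_chi2(ContingencyTable(2, 2, 2, 2)) == 0.0

    def test_worked_example_matches_scipy_oracle(self):
        t = ContingencyTable(3, 1, 0, 6)
        expected = chi2_contingency(
            np.array([[3, 1], [0, 6]]), correction=False
        ).statistic
        assert c_chi2(t) == pytest.approx(expected)
        assert c_chi2(t) == pytest.approx(6.428571428571429)

    def test_yates_is_never_larger_than_uncorrected(self):
        t = ContingencyTable(3, 1, 0, 6)
        assert c_chi2(t, correction=True) < c_chi2(t)

    def test_zero_marginal_degenerates_to_zero(self):
        assert c_chi2(ContingencyTable(0, 0, 3, 7)) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_random_tables_match_scipy(self, seed):
        rng = np.random.default_rng(100 + seed)
        a, b, c, d = (int(x) for x in rng.integers(1, 40, size=4))
        t = ContingencyTable(a, b, c, d)
        for corr in (False, True):
            ref = chi2_contingency(np.array([[a, b], [c, d]]), correction=corr)
            assert c_chi2(t, correction=corr) == pytest.approx(ref.statistic)


class TestDetect:
    def test_planted_class_is_the_only_significant_pair(self, ae_hierarchy):
        # class A (3 ingredients) all carry diarrhea; 7 background ingredients
        # carry nothing -> enumeration says exactly (A, diarrhea) and its
        # propagated parent (A, digestive) are significant
        edges = [("CLS:A", "CLS:root"), ("CLS:B", "CLS:root")]
        edges += [(f"ING:a{k}", "CLS:A") for k in range(3)]
        edges += [(f"ING:b{k}", "CLS:B") for k in range(7)]
        class_h = Hierarchy.from_edges(edges)
        table = AssociationTable(
            records=[
                AssociationRecord(
                    f"P{k}", "diarrhea", ingredient_ids=(f"ING:a{k}",),
                    ae_id="AE:diarrhea",
                )
                for k in range(3)
            ]
        )
        results = detect_class_effects(
            table,
            class_h,
            ae_hierarchy,
            ["CLS:A", "CLS:B"],
            sorted(ae_hierarchy.nodes - ae_hierarchy.roots),
        )
        sig = {(r.class_id, r.ae_id) for r in results if r.significant}
        assert sig == {("CLS:A", "AE:diarrhea"), ("CLS:A", "AE:digestive")}

    def test_small_class_fails_min_ingredient_filter(
        self, small_table, class_hierarchy, ae_hierarchy
    ):
        # digestive propagates to i4 (nausea), so statins (size 2) has PCR 1
        results = detect_class_effects(
            small_table,
            class_hierarchy,
            ae_hierarchy,
            ["CLS:statins"],
            ["AE:digestive"],
        )
        (r,) = results
        assert r.pcr == 1.0 and r.class_size == 2
        assert not r.passes_min_n and not r.significant

    def test_results_sorted_and_flags_conjoin(
        self, small_table, class_hierarchy, ae_hierarchy
    ):
        results = detect_class_effects(
            small_table,
            class_hierarchy,
            ae_hierarchy,
            ["CLS:statins", "CLS:glycosides"],
            ["AE:nausea", "AE:diarrhea"],
        )
        keys = [(r.class_id, r.ae_id) for r in results]
        assert keys == sorted(keys)
        for r in results:
            assert r.significant == (
                r.passes_pcr and r.passes_cprr and r.passes_chi2 and r.passes_min_n
            )

    def test_empty_class_list_gives_empty_result(
        self, small_table, class_hierarchy, ae_hierarchy
    ):
        assert (
            detect_class_effects(small_table, class_hierarchy, ae_hierarchy, [], [])
            == []
        )

    def test_unknown_class_id_is_an_error(
        self, small_table, class_hierarchy, ae_hierarchy
    ):
        with pytest.raises(Exception, match="CLS:bogus"):
            detect_class_effects(
                small_table, class_hierarchy, ae_hierarchy, ["CLS:bogus"], ["AE:nausea"]
            )

    def test_zero_background_passes_cprr_but_is_flagged(
        self, small_table, class_hierarchy, ae_hierarchy
    ):
        # diarrhea is carried only by glycosides members -> b = 0
        results = detect_class_effects(
            small_table,
            class_hierarchy,
            ae_hierarchy,
            ["CLS:glycosides"],
            ["AE:diarrhea"],
        )
        (r,) = results
        assert r.c_prr == math.inf and r.passes_cprr and r.zero_background

    def test_frame_carries_table_2_shaped_columns(
        self, small_table, class_hierarchy, ae_hierarchy
    ):
        results = detect_class_effects(
            small_table, class_hierarchy, ae_hierarchy,
            ["CLS:glycosides"], ["AE:diarrhea"],
        )
        df = results_to_frame(results)
        for col in ("class_id", "ae_id", "ingredient_no", "a", "b", "c", "d",
                    "pcr", "c_prr", "chi2", "significant", "n_pairs_tested"):
            assert col in df.columns
        assert df.loc[0, "ingredient_no"] == 3


class TestRankTopAes:
    def _table(self):
        recs = []
        for k in range(5):
            recs.append(
                AssociationRecord(f"P{k}", "nausea", ingredient_ids=(f"I{k % 2}",))
            )
        for k in range(2):
            recs.append(
                AssociationRecord(f"Q{k}", "rash", ingredient_ids=(f"I{k}",))
            )
        return AssociationTable(records=recs)

    def test_product_level_counts(self):
        assert rank_top_aes(self._table(), k=2, level="product") == [
            ("nausea", 5),
            ("rash", 2),
        ]

    def test_ingredient_level_collapses_counts(self):
        assert rank_top_aes(self._table(), k=2, level="ingredient") == [
            ("nausea", 2),
            ("rash", 2),
        ]

    def test_k_larger_than_distinct_aes_returns_all(self):
        assert len(rank_top_aes(self._table(), k=99, level="product")) == 2

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_count_and_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        recs = []
        for k in range(40):
            recs.append(
                AssociationRecord(
                    f"P{rng.integers(12)}",
                    f"ae{rng.integers(6)}",
                    ingredient_ids=(f"I{rng.integers(8)}",),
                )
            )
        table = AssociationTable(records=recs)
        counts = {}
        for r in table.records:  # oracle: direct count of distinct products
            counts.setdefault(r.ae_term_en, set()).add(r.product_id)
        expected = sorted(
            ((ae, len(ps)) for ae, ps in counts.items()),
            key=lambda kv: (-kv[1], kv[0]),
        )
        assert rank_top_aes(table, k=6, level="product") == expected
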
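import math

import numpy as np
import pytest
from scipy.stats import chi2_contingency

import oracles
from reactvec.cluster import Clustering
from reactvec.stats import (
    AnnotationSet,
    ContingencyTable,
    DegenerateTableError,
    background_probabilities,
    chi_squared_yates,
    compare_clusterings,
    contingency,
    enrichment,
    fisher_z,
    read_annotations_tsv,
    write_annotations_tsv,
)


def _clustering(assign):
    return Clustering(assign, max(assign.values()))


class TestContingency:
    def test_direct_count(self):
        c = _clustering({"i1": 1, "i2": 1, "i3": 2})
        a = AnnotationSet(
            "kw", {"i1": {"kw_a"}, "i2": {"kw_a", "kw_b"}, "i3": {"kw_b"}}
        )
        t = contingency(c, a)
        assert t.keywords == ("kw_a", "kw_b")
        assert t.f.tolist() == [[2, 1], [0, 1]]

    def test_unannotated_item_contributes_nothing(self):
        c = _clustering({"i1": 1, "i2": 2, "i3": 2})
        a = AnnotationSet("kw", {"i1": {"k"}, "i2": {"k"}})
        t = contingency(c, a)
        assert t.f.sum() == 2

    def test_empty_intersection_rejected(self):
        c = _clustering({"i1": 1})
        a = AnnotationSet("kw", {"other": {"k"}})
        with pytest.raises(ValueError, match="overlap"):
            contingency(c, a)


class TestYatesChiSquared:
    def test_perfectly_diagonal_2x2(self):
        # E = 5 in each cell; each cell contributes (|10-5|-0.5)^2/5
        t = ContingencyTable((1, 2), ("a", "b"), np.array([[10, 0], [0, 10]]))
        chi2, dof = chi_squared_yates(t)
        assert chi2 == pytest.approx(4 * 4.5**2 / 5)  # = 16.2
        assert dof == 1

    def test_agrees_with_scipy_on_2x2(self):
        f = np.array([[12, 7], [5, 21]])
        chi2, _ = chi_squared_yates(ContingencyTable((1, 2), ("a", "b"), f))
        ref = chi2_contingency(f, correction=True).statistic
        assert chi2 == pytest.approx(ref, abs=1e-9)

    def test_table_equal_to_expectation_gives_zero(self):
        t = ContingencyTable((1, 2), ("a", "b"), np.array([[4, 4], [4, 4]]))
        chi2, _ = chi_squared_yates(t)
        assert chi2 == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_cell_by_cell_oracle(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.integers(0, 30, size=(4, 6))
        f[0, 0] += 1  # guard against an all-zero first row
        t = ContingencyTable(tuple(range(1, 5)), tuple("abcdef"), f)
        chi2, dof = chi_squared_yates(t)
        assert chi2 == pytest.approx(oracles.yates_chi2(f), abs=1e-9)
        assert dof == 15

    def test_correction_is_conservative(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            f = rng.integers(1, 25, size=(3, 4))
            t = ContingencyTable((1, 2, 3), tuple("abcd"), f)
            yates, _ = chi_squared_yates(t)
            uncorrected = chi2_contingency(f, correction=False).statistic
            assert yates <= uncorrected + 1e-12

    def test_all_zero_row_dropped_with_warning(self):
        f = np.array([[5, 1], [0, 0], [2, 6]])
        t = ContingencyTable((1, 2, 3), ("a", "b"), f)
        with pytest.warns(UserWarning, match="all-zero"):
            chi2, dof = chi_squared_yates(t)
        assert dof == 1

    def test_degenerate_table_rejected(self):
        t = ContingencyTable((1,), ("a", "b"), np.array([[3, 4]]))
        with pytest.raises(DegenerateTableError):
            chi_squared_yates(t)


class TestFisherZ:
    def test_zero_statistic(self):
        assert fisher_z(0.0, 5) == -3.0

    def test_algebraic_zero_crossing(self):
        dof = 7
        assert fisher_z((2 * dof - 1) / 2, dof) == pytest.approx(0.0)

    def test_plug_in_value(self):
        assert fisher_z(72.2, 1) == pytest.approx(math.sqrt(144.4) - 1, abs=1e-9)

    def test_monotone_in_chi2(self):
        zs = [fisher_z(x, 10) for x in np.linspace(0, 50, 40)]
        assert all(a < b for a, b in zip(zs, zs[1:]))


class TestEnrichment:
    def test_hypergeometric_tail_matches_enumeration(self):
        # population 10, 4 carriers, cluster of 5, observed 3
        labels = {f"i{j}": (1 if j < 5 else 2) for j in range(10)}
        features = {f"i{j}": ({"F"} if j in (0, 1, 2, 5) else set()) for j in range(10)}
        results = enrichment(_clustering(labels), features)
        r = next(x for x in results if x.cluster == 1 and x.feature == "F")
        assert r.law_used == "hypergeometric"
        assert r.n == 3
        assert r.p_value == pytest.approx(66 / 252, abs=1e-12)
        assert r.p_value == pytest.approx(
            oracles.hypergeom_upper_tail(3, 10, 4, 5), abs=1e-12
        )

    def test_poisson_low_frequency_switch(self):
        # cluster of 20 in a population of 100; p = 0.05 -> lambda = 1
        labels = {f"i{j}": (1 if j < 20 else 2) for j in range(100)}
        carriers = {0, 1, 20, 21, 22}  # 2 in cluster 1
        features = {f"i{j}": ({"F"} if j in carriers else set()) for j in range(100)}
        results = enrichment(_clustering(labels), features)
        r = next(x for x in results if x.cluster == 1 and x.feature == "F")
        assert r.law_used == "poisson"
        assert r.p_value == pytest.approx(1 - 2 * math.exp(-1), abs=1e-9)
        assert r.p_value == pytest.approx(oracles.poisson_upper_tail(2, 1.0), abs=1e-9)

    def test_observed_zero_gives_pvalue_one(self):
        labels = {"a": 1, "b": 1, "c": 2, "d": 2}
        features = {"a": set(), "b": set(), "c": {"F"}, "d": {"F"}}
        results = enrichment(_clustering(labels), features)
        r = next(x for x in results if x.cluster == 1 and x.feature == "F")
        assert r.n == 0
        assert r.p_value == 1.0

    def test_background_probabilities_helper(self):
        features = {"a": {"F"}, "b": {"F", "G"}, "c": set(), "d": {"G"}}
        p = background_probabilities(features)
        assert p == {"F": 0.5, "G": 0.5}

    def test_feature_missing_from_background_rejected(self):
        labels = {"a": 1, "b": 2}
        features = {"a": {"F"}, "b": {"F"}}
        with pytest.raises(KeyError, match="F"):
            enrichment(_clustering(labels), features, background={"G": 0.5})

    def test_bonferroni_never_below_raw(self):
        labels = {f"i{j}": (j % 3) + 1 for j in range(30)}
        features = {f"i{j}": {f"F{j % 5}"} for j in range(30)}
        raw = enrichment(_clustering(labels), features)
        adj = enrichment(_clustering(labels), features, correction="bonferroni")
        for r, q in zip(raw, adj):
            assert q.p_value >= r.p_value - 1e-15


class TestCompareClusterings:
    def test_random_annotations_give_small_z(self):
        rng = np.random.default_rng(0)
        items = [f"i{j}" for j in range(1000)]
        c = _clustering({i: int(rng.integers(1, 6)) for i in items})
        a = AnnotationSet(
            "null", {i: {f"kw{int(rng.integers(5))}"} for i in items}
        )
        table = compare_clusterings({"c": c}, [a])
        assert abs(table.loc["c", "null"]) < 3

    def test_perfect_annotations_give_large_z(self):
        labels = {f"i{j}": (j % 5) + 1 for j in range(100)}
        c = _clustering(labels)
        a = AnnotationSet("perfect", {i: {f"kw{lab}"} for i, lab in labels.items()})
        table = compare_clusterings({"c": c}, [a])
        assert table.loc["c", "perfect"] > 10

    def test_output_shape(self):
        labels = {f"i{j}": (j % 2) + 1 for j in range(40)}
        c1, c2 = _clustering(labels), _clustering({k: 2 - v + 1 for k, v in labels.items()})
        a1 = AnnotationSet("s1", {i: {f"k{lab}"} for i, lab in labels.items()})
        a2 = AnnotationSet("s2", {i: {f"m{(lab + 1) % 2}"} for i, lab in labels.items()})
        table = compare_clusterings({"x": c1, "y": c2}, [a1, a2])
        assert table.shape == (2, 2)


class TestAnnotationIO:
    def test_tsv_round_trip(self):
        sets = [
            AnnotationSet("brenda", {"r1": {"oxidation"}, "r2": {"hydrolysis", "x y"}}),
            AnnotationSet("go", {"r1": {"GO:0016491"}}),
        ]
        back = read_annotations_tsv(write_annotations_tsv(sets))
        assert set(back) == {"brenda", "go"}
        assert back["brenda"].assignments == sets[0].assignments
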
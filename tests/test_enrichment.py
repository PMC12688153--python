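"""Subset algebra, enrichment ratios, ROC, overlap and GO fold enrichment."""

import numpy as np
import pandas as pd
import pytest

from bcoi.enrichment import (
    GOTable,
    LabelTable,
    basis_terms,
    enrichment_ratio,
    filter_overlap_matrix,
    go_fold_enrichment,
    roc_scan,
    subset_algebra,
    subset_passrate_table,
)
from bcoi.synthetic import SyntheticCohortSpec, make_cohort


def cohort_go_table(cohort):
    ann = {p: set(g) for p, g in
           cohort.go_annotations.groupby("protein_id")["term_id"].apply(set).items()}
    hier = {}
    for t, p in zip(cohort.go_hierarchy["term_id"],
                    cohort.go_hierarchy["parent_id"]):
        hier.setdefault(t, set()).add(p)
    return GOTable(annotations=ann, hierarchy=hier)


class TestSubsetAlgebra:
    def test_annotation_source_counts(self):
        out = subset_algebra({"n_total": 20503, "n_E": 4451, "n_T": 383,
                              "n_both": 24})
        assert out["n_ET"] == 4810
        assert out["n_NET"] == 15693

    def test_disjoint_sets_add(self):
        out = subset_algebra({"n_total": 10, "n_E": 3, "n_T": 2, "n_both": 0})
        assert out["n_ET"] == 5 and out["n_NET"] == 5

    def test_matches_bruteforce_sets_on_random_tables(self):
        rng = np.random.default_rng(21)
        n = 500
        df = pd.DataFrame({
            "protein_id": [f"P{i}" for i in range(n)],
            "enzyme": rng.integers(0, 2, n),
            "transporter": rng.integers(0, 2, n),
            "ph_dependent": rng.integers(0, 2, n)})
        lt = LabelTable(df)
        out = subset_algebra(lt)
        et = {p for p, e, t in zip(df.protein_id, df.enzyme, df.transporter)
              if e or t}
        assert out["n_ET"] == len(et) == len(lt.et)
        assert out["n_NET"] == n - len(et) == len(lt.net)
        assert lt.et | lt.net == lt.all_proteins
        assert not (lt.et & lt.net)

    def test_duplicate_ids_rejected(self):
        df = pd.DataFrame({"protein_id": ["A", "A"], "enzyme": [0, 1],
                           "transporter": [0, 0], "ph_dependent": [0, 0]})
        with pytest.raises(ValueError, match="duplicate"):
            LabelTable(df)


class TestEnrichmentRatio:
    def test_equal_rates_give_unity(self):
        assert enrichment_ratio(10, 100, 50, 500).ratio == pytest.approx(1.0)

    def test_forced_arithmetic(self):
        assert enrichment_ratio(20, 100, 50, 1000).ratio == pytest.approx(4.0)

    def test_scale_invariance(self):
        a = enrichment_ratio(20, 100, 50, 1000).ratio
        b = enrichment_ratio(60, 300, 150, 3000).ratio
        assert a == pytest.approx(b)

    def test_zero_reference_pass_censored(self):
        r = enrichment_ratio(5, 100, 0, 1000)
        assert r.censored and r.ratio is None

    def test_zero_sizes_rejected(self):
        with pytest.raises(ValueError):
            enrichment_ratio(1, 0, 1, 10)

    def test_recovers_planted_threefold_passrate(self):
        spec = SyntheticCohortSpec(
            n_proteins=5000,
            pass_prob_et={"f": 0.6}, pass_prob_net={"f": 0.2},
            query_filter="f")
        c = make_cohort(spec, seed=31)
        lt = c.label_table()
        passed = set(c.passes.index[c.passes["f"]])
        r = enrichment_ratio(len(passed & lt.et), len(lt.et),
                             len(passed & lt.net), len(lt.net))
        assert 2.5 <= r.ratio <= 3.5

    def test_null_rates_give_unity_within_ci(self):
        spec = SyntheticCohortSpec(
            n_proteins=5000,
            pass_prob_et={"f": 0.3}, pass_prob_net={"f": 0.3},
            query_filter="f")
        c = make_cohort(spec, seed=32)
        lt = c.label_table()
        passed = set(c.passes.index[c.passes["f"]])
        r = enrichment_ratio(len(passed & lt.et), len(lt.et),
                             len(passed & lt.net), len(lt.net))
        assert r.ratio == pytest.approx(1.0, abs=0.12)


class TestRocScan:
    def test_perfect_and_trivial_classifiers(self):
        et, net = {"a", "b"}, {"c", "d", "e"}
        df = roc_scan({"perfect": {"a", "b"},
                       "all": {"a", "b", "c", "d", "e"},
                       "none": set()}, et, net).set_index("cell")
        assert tuple(df.loc["perfect", ["tpr", "fpr"]]) == (1.0, 0.0)
        assert tuple(df.loc["all", ["tpr", "fpr"]]) == (1.0, 1.0)
        assert tuple(df.loc["none", ["tpr", "fpr"]]) == (0.0, 0.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            roc_scan({"f": set()}, set(), {"a"})

    def test_recovers_planted_rates(self):
        spec = SyntheticCohortSpec(
            n_proteins=2000,
            pass_prob_et={"f": 0.8}, pass_prob_net={"f": 0.2},
            go_terms={"GO:NULL": (0.1, 1.0)}, query_filter="f")
        c = make_cohort(spec, seed=33)
        lt = c.label_table()
        passed = set(c.passes.index[c.passes["f"]])
        df = roc_scan({"f": passed}, lt.et, lt.net)
        assert 0.75 <= df.loc[0, "tpr"] <= 0.85
        assert 0.15 <= df.loc[0, "fpr"] <= 0.25

    def test_rates_nested_as_threshold_relaxes(self):
        rng = np.random.default_rng(3)
        scores = {f"P{i}": rng.random() for i in range(300)}
        et = {p for p in scores if rng.random() < 0.3}
        net = set(scores) - et
        cells = {dq: {p for p, s in scores.items() if s >= dq}
                 for dq in (0.8, 0.5, 0.2)}
        df = roc_scan(cells, et, net).set_index("cell")
        assert df.loc[0.2, "tpr"] >= df.loc[0.5, "tpr"] >= df.loc[0.8, "tpr"]
        assert df.loc[0.2, "fpr"] >= df.loc[0.5, "fpr"] >= df.loc[0.8, "fpr"]


class TestOverlapMatrix:
    def test_identical_filters_ratio_n_over_k(self):
        passed = {f"P{i}" for i in range(20)}
        mat = filter_overlap_matrix({"a": passed, "b": passed}, 100)
        assert mat.loc["a", "b"] == pytest.approx(100 / 20)

    def test_disjoint_filters_ratio_zero(self):
        mat = filter_overlap_matrix({"a": {"x"}, "b": {"y"}}, 100)
        assert mat.loc["a", "b"] == 0.0

    def test_zero_pass_filter_censored(self):
        mat = filter_overlap_matrix({"a": {"x"}, "b": set()}, 100)
        assert np.isnan(mat.loc["a", "b"])

    def test_independent_filters_near_unity(self):
        spec = SyntheticCohortSpec(
            n_proteins=10000, fraction_et=0.0,
            pass_prob_net={"a": 0.3, "b": 0.4},
            pass_prob_et={"a": 0.3, "b": 0.4}, query_filter="a")
        c = make_cohort(spec, seed=34)
        sets = {f: set(c.passes.index[c.passes[f]]) for f in ("a", "b")}
        mat = filter_overlap_matrix(sets, 10000)
        assert 0.8 <= mat.loc["a", "b"] <= 1.2


class TestGOFoldEnrichment:
    def simple_table(self):
        return GOTable(
            annotations={"p1": {"leaf"}, "p2": {"leaf"}, "p3": {"mid"},
                         "p4": {"root"}},
            hierarchy={"leaf": {"mid"}, "mid": {"root"}})

    def test_query_equals_reference_unity(self):
        go = self.simple_table()
        df = go_fold_enrichment({"p1", "p2", "p3", "p4"},
                                {"p1", "p2", "p3", "p4"}, go)
        assert (df["fold"] == 1.0).all()

    def test_leaf_annotation_propagates_to_ancestors(self):
        go = self.simple_table()
        prop = go.propagated()
        assert prop["p1"] == {"leaf", "mid", "root"}
        df = go_fold_enrichment({"p1"}, {"p1", "p2", "p3", "p4"},
                                go).set_index("term_id")
        assert df.loc["root", "reference_hits"] == 4
        assert df.loc["mid", "reference_hits"] == 3

    def test_query_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            go_fold_enrichment({"p9"}, {"p1"}, self.simple_table())

    def test_cyclic_hierarchy_rejected(self):
        go = GOTable(annotations={"p": {"a"}},
                     hierarchy={"a": {"b"}, "b": {"a"}})
        with pytest.raises(ValueError, match="cycle"):
            go.propagated()

    def test_basis_restriction_fixes_output_rows(self):
        go = self.simple_table()
        df = go_fold_enrichment({"p1"}, {"p1", "p2", "p3", "p4"}, go,
                                basis=["root", "leaf", "GO:ABSENT"])
        assert list(df["term_id"]) == ["root", "leaf", "GO:ABSENT"]
        assert np.isnan(df.set_index("term_id").loc["GO:ABSENT", "fold"])

    def test_basis_terms_cover_reference_annotations(self):
        go = self.simple_table()
        assert basis_terms({"p1", "p3"}, go) == ["leaf", "mid", "root"]

    def test_recovers_planted_threefold(self):
        c = make_cohort(SyntheticCohortSpec(n_proteins=2000), seed=35)
        go = cohort_go_table(c)
        lt = c.label_table()
        # query = NET proteins with a pass, assessed against NET as reference
        df = go_fold_enrichment(c.query_set, lt.net,
                                go).set_index("term_id")
        assert 2.4 <= df.loc["GO:QRY3", "fold"] <= 3.6
        assert df.loc["GO:NULL", "fold"] == pytest.approx(1.0, abs=0.15)

    def test_uniform_annotation_concentrates_at_unity(self):
        rng = np.random.default_rng(36)
        n = 5000
        ids = [f"P{i}" for i in range(n)]
        terms = [f"T{k}" for k in range(8)]
        ann = {p: {t for t in terms if rng.random() < 0.2} for p in ids}
        go = GOTable(annotations=ann, hierarchy={t: {"root"} for t in terms})
        query = {p for p in ids if rng.random() < 0.2}
        df = go_fold_enrichment(query, set(ids), go)
        folds = df.loc[df["term_id"] != "root", "fold"].dropna()
        assert abs(folds.mean() - 1.0) < 0.1


def test_subset_passrate_table_shape():
    results = {"f1": {"a", "b"}, "f2": {"b"}}
    subsets = {"E": {"a", "c"}, "NET": {"b", "d"}}
    df = subset_passrate_table(results, subsets)
    assert len(df) == 4
    row = df[(df["filter"] == "f1") & (df["subset"] == "E")].iloc[0]
    assert row["pct_pass"] == pytest.approx(50.0)
    assert row["pct_fail"] == pytest.approx(50.0)
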
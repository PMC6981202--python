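import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from myometa.reference import (
    load_acute_aerobic_reference, load_training_reference,
)
from myometa.setops import (
    SignificanceQuery, complex_projection, concordance_overlap,
    healthy_specific, ora_hypergeometric, significant_set, top_n_genes,
    venn_counts,
)
from myometa.types import ComplexMap, GeneSetCollection, STATUS_OK

from oracles import hypergeom_tail_enumeration, venn_by_membership


def _meta(rows):
    frame = pd.DataFrame(rows)
    if "status" not in frame:
        frame["status"] = STATUS_OK
    return frame


class TestSignificantSet:
    def test_strong_acute_responder_included(self):
        table = load_acute_aerobic_reference()
        got = significant_set(table, fdr_threshold=0.01, direction="UP")
        assert "NR4A3" in got
        assert got == {"NR4A3", "EGR1", "FOS", "MAFF", "CYR61"}

    def test_flat_training_response_excluded(self):
        # NR4A3 under resistance training: logFC -0.03, FDR 0.87
        table = _meta([{"gene": "NR4A3", "mu": -0.03, "fdr": 0.87}])
        assert significant_set(table, fdr_threshold=0.01) == set()

    def test_empty_table_gives_empty_set(self):
        table = _meta([{"gene": "x", "mu": 1.0, "fdr": 0.5}]).iloc[:0]
        assert significant_set(table, fdr_threshold=0.01) == set()

    def test_monotone_in_threshold(self, rng):
        table = _meta([{"gene": f"g{i}", "mu": rng.normal(),
                        "fdr": rng.random()} for i in range(100)])
        small = significant_set(table, fdr_threshold=0.05)
        large = significant_set(table, fdr_threshold=0.3)
        assert small <= large

    def test_direction_filters_sign(self):
        table = _meta([{"gene": "up", "mu": 1.0, "fdr": 0.001},
                       {"gene": "down", "mu": -1.0, "fdr": 0.001}])
        assert significant_set(table, fdr_threshold=0.01, direction="UP") == {"up"}
        assert significant_set(table, fdr_threshold=0.01, direction="DOWN") == {"down"}

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            SignificanceQuery(0.0)


class TestVennCounts:
    def test_two_set_hand_example(self):
        counts = venn_counts({"X": {"A", "B"}, "Y": {"B", "C"}})
        assert counts[frozenset({"X"})] == 1
        assert counts[frozenset({"Y"})] == 1
        assert counts[frozenset({"X", "Y"})] == 1

    def test_disjoint_sets_have_empty_intersections(self):
        counts = venn_counts({"X": {1, 2}, "Y": {3}})
        assert counts[frozenset({"X", "Y"})] == 0

    def test_matches_membership_enumeration_oracle(self, rng):
        sets = {name: set(rng.integers(0, 30, size=rng.integers(1, 20)))
                for name in "ABC"}
        counts = venn_counts(sets)
        oracle = venn_by_membership(sets)
        for region, n in counts.items():
            assert n == oracle.get(region, 0)
        assert sum(counts.values()) == len(set().union(*sets.values()))

    def test_set_count_bounds(self):
        with pytest.raises(ValueError):
            venn_counts({"A": {1}})
        with pytest.raises(ValueError):
            venn_counts({str(i): {1} for i in range(6)})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.sets(st.integers(0, 20)), min_size=2, max_size=5))
    def test_region_counts_sum_to_union(self, raw_sets):
        sets = {f"S{i}": s for i, s in enumerate(raw_sets)}
        counts = venn_counts(sets)
        assert sum(counts.values()) == len(set().union(*sets.values()))


class TestTopN:
    def test_printed_acute_aerobic_ranking(self):
        table = load_acute_aerobic_reference()
        up, down = top_n_genes(table, 5)
        assert up == ["NR4A3", "EGR1", "FOS", "MAFF", "CYR61"]
        assert down[0] == "GADD45G"

    def test_n_beyond_table_returns_full_ordering(self):
        table = _meta([{"gene": "a", "mu": 1.0, "fdr": 0.1},
                       {"gene": "b", "mu": 0.5, "fdr": 0.1}])
        up, down = top_n_genes(table, 10)
        assert up == ["a", "b"]
        assert down == ["b", "a"]

    def test_fdr_then_gene_id_break_ties(self):
        table = _meta([{"gene": "zz", "mu": 1.0, "fdr": 0.01},
                       {"gene": "aa", "mu": 1.0, "fdr": 0.05},
                       {"gene": "mm", "mu": 1.0, "fdr": 0.01}])
        up, _ = top_n_genes(table, 3)
        assert up == ["mm", "zz", "aa"]


class TestHealthySpecific:
    def test_reference_aerobic_and_resistance_rows(self):
        ref = load_training_reference()
        aerobic = healthy_specific(ref[("aerobic", "healthy")],
                                   ref[("aerobic", "impaired")], 0.01, 0.9)
        resistance = healthy_specific(ref[("resistance", "healthy")],
                                      ref[("resistance", "impaired")], 0.01, 0.9)
        assert aerobic == {"GUCY1B1", "KANSL3", "ARNT", "TOP2B", "IGIP"}
        assert resistance == {"COL6A6", "APLNR", "COL4A2", "PTGDS", "ABCG1"}

    def test_gene_flat_in_healthy_not_flagged(self):
        ref = load_training_reference()
        aerobic = healthy_specific(ref[("aerobic", "healthy")],
                                   ref[("aerobic", "impaired")], 0.01, 0.9)
        assert "PTGDS" not in aerobic  # aerobic healthy FDR 0.82

    def test_empty_inputs(self):
        empty = _meta([{"gene": "x", "mu": 0.0, "fdr": 1.0}]).iloc[:0]
        assert healthy_specific(empty, empty) == set()


class TestConcordance:
    def test_intersection_across_direction_sets(self):
        got = concordance_overlap(
            up_sets=[{"NR4A3", "EGR1"}, {"NR4A3", "MAFF"}],
            down_sets=[{"NR4A3"}],
        )
        assert got == {"NR4A3"}

    def test_any_empty_set_empties_the_overlap(self):
        assert concordance_overlap([{"a"}, set()], [{"a"}]) == set()

    def test_identical_sets_pass_through(self):
        assert concordance_overlap([{"a", "b"}], [{"a", "b"}]) == {"a", "b"}

    def test_requires_both_directions(self):
        with pytest.raises(ValueError):
            concordance_overlap([], [{"a"}])


class TestORA:
    def _collection(self, **sets):
        return GeneSetCollection({k: ("", list(v)) for k, v in sets.items()})

    def test_complete_containment_hand_example(self):
        universe = {f"g{i}" for i in range(10)}
        inside = {f"g{i}" for i in range(5)}
        res = ora_hypergeometric(inside, universe,
                                 self._collection(hit=inside))
        assert res.iloc[0]["p"] == pytest.approx(1 / 252)

    def test_disjoint_query_is_anti_enriched(self):
        universe = {f"g{i}" for i in range(10)}
        res = ora_hypergeometric({"g0", "g1"}, universe,
                                 self._collection(other={"g8", "g9"}))
        assert res.iloc[0]["p"] > 0.5

    def test_universe_sized_set_is_certain(self):
        universe = {f"g{i}" for i in range(8)}
        res = ora_hypergeometric({"g0"}, universe,
                                 self._collection(all=universe))
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            ora_hypergeometric({"x"}, {"a", "b"}, self._collection(s={"a"}))

    def test_matches_exhaustive_enumeration(self, rng):
        for trial in range(5):
            n_universe = int(rng.integers(6, 16))
            universe = [f"g{i}" for i in range(n_universe)]
            gene_set = list(rng.choice(universe,
                                       size=int(rng.integers(2, n_universe)),
                                       replace=False))
            query = list(rng.choice(universe,
                                    size=int(rng.integers(1, min(8, n_universe))),
                                    replace=False))
            res = ora_hypergeometric(set(query), set(universe),
                                     self._collection(s=gene_set))
            overlap = len(set(query) & set(gene_set))
            expected = hypergeom_tail_enumeration(universe, gene_set,
                                                  len(query), overlap)
            assert res.iloc[0]["p"] == pytest.approx(expected, rel=1e-10)


class TestComplexProjection:
    def _results(self, mus):
        return _meta([{"gene": g, "mu": mu, "fdr": 0.5}
                      for g, mu in mus.items()])

    def test_mean_over_member_genes(self):
        cmap = ComplexMap({"CX": ["g1", "g2"]})
        out = complex_projection(
            {"acute_aerobic": self._results({"g1": 0.2, "g2": 0.4})}, cmap)
        assert out.loc["CX", "ACUTE_AEROBIC"] == pytest.approx(0.3)

    def test_unmeasured_member_ignored(self):
        cmap = ComplexMap({"CX": ["g1", "ghost"]})
        out = complex_projection(
            {"inactivity": self._results({"g1": 0.2})}, cmap)
        assert out.loc["CX", "INACTIVITY"] == pytest.approx(0.2)

    def test_cancellation_and_missing_protocol(self):
        cmap = ComplexMap({"CX": ["g1", "g2"], "CY": ["ghost"]})
        out = complex_projection(
            {"inactivity": self._results({"g1": 0.1, "g2": -0.1})}, cmap)
        assert out.loc["CX", "INACTIVITY"] == pytest.approx(0.0)
        assert np.isnan(out.loc["CY", "INACTIVITY"])
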
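from itertools import combinations
from math import comb

import numpy as np
import pytest

from depath.enrich import (
    GeneSetCollection,
    build_term_summary,
    hypergeometric_enrich,
    read_gmt,
    term_overlap_distance,
    write_gmt,
)


def collection(sets, size_min=1, size_max=2000):
    return GeneSetCollection(dict(sets), size_min=size_min, size_max=size_max)


def enumeration_tail(N, K, n, k):
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact combinatorial sum."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / total


class TestReadGmt:
    def test_two_sets(self, tmp_path):
        path = tmp_path / "c.gmt"
        path.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg2\tg4\n")
        coll = read_gmt(path)
        assert coll.names == ["setA", "setB"]
        assert coll.sets["setB"] == ["g2", "g4"]

    def test_duplicate_member_stored_once(self, tmp_path):
        path = tmp_path / "c.gmt"
        path.write_text("setA\tdesc\tg1\tg1\tg2\n")
        assert read_gmt(path).sets["setA"] == ["g1", "g2"]

    def test_single_column_line_reports_line_number(self, tmp_path):
        path = tmp_path / "c.gmt"
        path.write_text("setA\tdesc\tg1\nbroken_line\n")
        with pytest.raises(ValueError, match=":2:"):
            read_gmt(path)

    def test_empty_set_dropped_with_warning(self, tmp_path):
        path = tmp_path / "c.gmt"
        path.write_text("setA\tdesc\tg1\nempty\tdesc\n")
        with pytest.warns(UserWarning, match="empty set"):
            coll = read_gmt(path)
        assert coll.names == ["setA"]

    def test_round_trip(self, tmp_path):
        coll = collection({"s1": ["a", "b", "c"], "s2": ["b", "d"]})
        coll.category = "cat"
        path = tmp_path / "out.gmt"
        write_gmt(coll, path)
        again = read_gmt(path)
        assert again.sets == coll.sets


class TestHypergeometricEnrich:
    def test_exact_worked_example(self):
        # N=20, K=5, n=6, k=3 -> p = 5090/38760
        background = [f"b{i}" for i in range(20)]
        members = background[:5]
        query = background[:3] + background[5:8]  # overlap 3, query 6
        coll = collection({"S": members})
        out = hypergeometric_enrich(query, coll, background)
        assert out.loc[0, "k"] == 3 and out.loc[0, "K"] == 5
        assert out.loc[0, "p_value"] == pytest.approx(5090 / 38760, abs=1e-12)

    def test_zero_overlap_p_one(self):
        background = [f"b{i}" for i in range(12)]
        coll = collection({"S": background[:4]})
        out = hypergeometric_enrich(background[4:8], coll, background)
        assert out.loc[0, "k"] == 0 and out.loc[0, "p_value"] == pytest.approx(1.0)

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 5, 5), (12, 6, 4), (12, 4, 7)])
    def test_matches_enumeration_oracle(self, N, K, n):
        background = [f"b{i}" for i in range(N)]
        coll = collection({"S": background[:K]})
        for k in range(0, min(K, n) + 1):
            query = background[:k] + background[K : K + (n - k)]
            out = hypergeometric_enrich(query, coll, background)
            assert out.loc[0, "p_value"] == pytest.approx(
                enumeration_tail(N, K, n, k), abs=1e-12
            )

    def test_query_equals_set_is_minimal_p(self):
        # brute force: among all same-size queries on a 10-gene universe,
        # the set itself achieves the smallest enrichment p
        background = [f"b{i}" for i in range(10)]
        members = background[:4]
        coll = collection({"S": members})
        p_self = hypergeometric_enrich(members, coll, background).loc[0, "p_value"]
        for query in combinations(background, 4):
            p = hypergeometric_enrich(list(query), coll, background).loc[0, "p_value"]
            assert p_self <= p + 1e-15

    def test_size_window_applied(self):
        background = [f"b{i}" for i in range(30)]
        coll = GeneSetCollection(
            {"small": background[:2], "ok": background[:20]}, size_min=5, size_max=25
        )
        out = hypergeometric_enrich(background[:5], coll, background)
        assert list(out["set_name"]) == ["ok"]

    def test_planted_set_ranks_first(self):
        rng = np.random.default_rng(0)
        background = [f"b{i}" for i in range(500)]
        planted = background[:40]
        sets = {"planted": planted}
        for j in range(30):
            sets[f"rand{j}"] = list(rng.choice(background, size=40, replace=False))
        coll = GeneSetCollection(sets, size_min=1, size_max=2000)
        # query: half from the planted set, half random elsewhere
        query = planted[:20] + list(rng.choice(background[40:], 20, replace=False))
        out = hypergeometric_enrich(query, coll, background)
        assert out.loc[0, "set_name"] == "planted"

    def test_empty_query_rejected(self):
        coll = collection({"S": ["a", "b"]})
        with pytest.raises(ValueError, match="query"):
            hypergeometric_enrich(["zz"], coll, ["a", "b", "c"])


class TestTermOverlapDistance:
    def test_identical_zero(self):
        assert term_overlap_distance(["a", "b"], ["a", "b"]) == 0.0

    def test_disjoint_one(self):
        assert term_overlap_distance(["a"], ["b"]) == 1.0

    def test_formula(self):
        a = ["g1", "g2", "g3", "g4"]
        b = ["g1", "g2", "g5", "g6", "g7", "g8"]
        assert term_overlap_distance(a, b) == pytest.approx(0.5)
        assert term_overlap_distance(a, b, method="jaccard") == pytest.approx(1 - 2 / 8)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            term_overlap_distance([], ["a"])


class TestBuildTermSummary:
    def enriched_frame(self, overlaps):
        import pandas as pd

        return pd.DataFrame(
            {
                "set_name": list(overlaps),
                "k": [len(v) for v in overlaps.values()],
                "K": [len(v) for v in overlaps.values()],
                "n": 10,
                "N": 100,
                "p_value": 0.001,
                "fdr": 0.01,
                "overlap_genes": list(overlaps.values()),
            }
        )

    def test_identical_terms_edge_and_zero_height(self):
        query = ["g1", "g2", "g3"]
        enriched = self.enriched_frame({"t1": query, "t2": query})
        out = build_term_summary(enriched, query)
        assert len(out["edges"]) == 1
        assert out["linkage"][0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_terms_no_edge(self):
        query = ["g1", "g2", "g3", "g4"]
        enriched = self.enriched_frame({"t1": ["g1", "g2"], "t2": ["g3", "g4"]})
        out = build_term_summary(enriched, query, edge_threshold=0.5)
        assert len(out["edges"]) == 0
        assert out["newick"] is not None

    def test_exactly_one_overlapping_pair(self):
        query = [f"g{i}" for i in range(8)]
        enriched = self.enriched_frame(
            {
                "t1": ["g0", "g1", "g2"],
                "t2": ["g0", "g1", "g3"],  # overlap 2/3 with t1
                "t3": ["g5", "g6", "g7"],
            }
        )
        out = build_term_summary(enriched, query, edge_threshold=0.5)
        assert len(out["edges"]) == 1
        assert set(out["edges"].loc[0, ["source", "target"]]) == {"t1", "t2"}

    def test_nodes_carry_significance(self):
        query = ["g1", "g2"]
        enriched = self.enriched_frame({"t1": ["g1"], "t2": ["g2"]})
        out = build_term_summary(enriched, query)
        assert out["nodes"]["neg_log10_fdr"].tolist() == pytest.approx([2.0, 2.0])


class TestBHCalibration:
    def test_null_simulation_controls_fdr(self):
        # 2000 independent null sets: BH at q keeps the p<0.05 fraction
        # near nominal before adjustment and rejects ~nothing after
        rng = np.random.default_rng(7)
        background = [f"b{i}" for i in range(400)]
        sets = {
            f"s{j}": list(rng.choice(background, size=20, replace=False))
            for j in range(2000)
        }
        coll = GeneSetCollection(sets, size_min=1, size_max=2000)
        query = list(rng.choice(background, size=40, replace=False))
        out = hypergeometric_enrich(query, coll, background)
        # hypergeometric p-values are discrete and conservative: the
        # p<0.05 fraction must not exceed ~0.05 + MC slack
        assert (out["p_value"] < 0.05).mean() < 0.07
        assert (out["fdr"] < 0.05).mean() < 0.02
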
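"""Expression ranking, marker detection, target intersection, RBH."""

import numpy as np
import pandas as pd
import pytest

from mbchip.expression import (
    find_markers,
    gene_lengths_from_models,
    intersect_targets_with_markers,
    rank_by_length_normalized,
    reciprocal_best_hits,
)
from mbchip.models import CountTable, GeneModel
from mbchip.regions import GenomicInterval
from mbchip.simulate import generate_hit_tables, generate_sc_counts

from .oracles import rbh_by_definition


def table_from(counts: dict, lengths: dict) -> CountTable:
    return CountTable(
        counts=pd.DataFrame({"s1": pd.Series(counts)}),
        lengths=pd.Series(lengths),
    )


class TestLengthNormalizedRanking:
    def test_normalization_beats_raw_count(self):
        t = table_from({"A": 100, "B": 30}, {"A": 10, "B": 1})
        ranked = rank_by_length_normalized(t, top_n=40)
        assert ranked["gene_id"].tolist() == ["B", "A"]
        assert ranked["normalized_value"].tolist() == [30.0, 10.0]
        assert ranked["rank"].tolist() == [1, 2]

    def test_tie_break_and_permutation_invariance(self, rng):
        genes = [f"g{i:03d}" for i in range(60)]
        counts = {g: int(rng.integers(1, 6)) * 10 for g in genes}
        lengths = {g: 10 for g in genes}  # many exact ties
        ref = rank_by_length_normalized(table_from(counts, lengths), top_n=60)
        for _ in range(5):
            perm = list(genes)
            rng.shuffle(perm)
            shuffled = table_from({g: counts[g] for g in perm}, {g: lengths[g] for g in perm})
            again = rank_by_length_normalized(shuffled, top_n=60)
            assert again["gene_id"].tolist() == ref["gene_id"].tolist()

    def test_missing_length_excluded_with_warning(self):
        t = CountTable(
            counts=pd.DataFrame({"s1": pd.Series({"A": 5, "B": 7})}),
            lengths=pd.Series({"A": 10}),
        )
        with pytest.warns(UserWarning, match="1 genes"):
            ranked = rank_by_length_normalized(t, top_n=10)
        assert ranked["gene_id"].tolist() == ["A"]

    def test_exonic_length_preferred_over_span(self):
        g = GeneModel(
            gene_id="X",
            span=GenomicInterval("c", 0, 10_000, "+"),
            exons=(GenomicInterval("c", 0, 500, "+"), GenomicInterval("c", 9_000, 10_000, "+")),
        )
        bare = GeneModel(gene_id="Y", span=GenomicInterval("c", 0, 2_000, "+"))
        lengths = gene_lengths_from_models([g, bare])
        assert lengths["X"] == 1_500
        assert lengths["Y"] == 2_000


class TestFindMarkers:
    def test_planted_marker_detected(self):
        m, labels, truth = generate_sc_counts(
            n_clusters=3, cells_per_cluster=100, n_genes=300, markers_per_cluster=2,
            fold=8.0, nb_dispersion=0.5, seed=11,
        )
        res = find_markers(m, labels)
        detected = {(r.gene_id, r.cluster) for r in res.itertuples() if r.is_marker}
        planted = {(g, c) for c, gs in truth.items() for g in gs}
        assert planted <= detected

    def test_identical_distribution_not_a_marker(self, rng):
        counts = pd.DataFrame(
            rng.poisson(5.0, size=(60, 20)),
            index=[f"c{i}" for i in range(60)],
            columns=[f"g{i}" for i in range(20)],
        )
        labels = pd.Series([0] * 30 + [1] * 30, index=counts.index)
        res = find_markers(CountTable(counts=counts), labels)
        # exchangeable clusters: nothing survives the effect filter / test
        assert not res["is_marker"].any()

    def test_small_cluster_excluded_with_warning(self):
        m, labels, _ = generate_sc_counts(
            n_clusters=3, cells_per_cluster=20, n_genes=100, markers_per_cluster=1, seed=5
        )
        labels.iloc[:18] = 99  # shrink cluster 0 to 2 cells, add a big cluster 99
        with pytest.warns(UserWarning, match="fewer than"):
            res = find_markers(m, labels)
        assert 0 not in set(res["cluster"])

    def test_single_cluster_rejected(self):
        counts = pd.DataFrame(np.ones((6, 4), dtype=int))
        labels = pd.Series([0] * 6)
        with pytest.raises(ValueError):
            find_markers(CountTable(counts=counts), labels)

    def test_adjusted_p_dominates_raw(self):
        m, labels, _ = generate_sc_counts(
            n_clusters=2, cells_per_cluster=50, n_genes=200, markers_per_cluster=3, seed=9
        )
        res = find_markers(m, labels)
        assert (res["p_adj"] >= res["p"]).all()
        assert res["p"].between(0, 1).all()

    def test_bh_no_less_powerful_than_bonferroni(self):
        m, labels, _ = generate_sc_counts(
            n_clusters=2, cells_per_cluster=60, n_genes=200, markers_per_cluster=4, seed=13
        )
        bonf = find_markers(m, labels, correction="bonferroni")
        bh = find_markers(m, labels, correction="bh")
        assert bh["is_marker"].sum() >= bonf["is_marker"].sum()


def marker_frame(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "cluster", "effect", "p", "p_adj", "is_marker"]
    )


class TestIntersection:
    def make_markers(self, membership):
        rows = []
        for gene, clusters in membership.items():
            for c in (1, 2, 6, 7, 0, 3):
                rows.append(
                    {
                        "gene_id": gene,
                        "cluster": c,
                        "effect": 1.0,
                        "p": 1e-9 if c in clusters else 0.9,
                        "p_adj": 1e-7 if c in clusters else 1.0,
                        "is_marker": c in clusters,
                    }
                )
        return marker_frame(rows)

    def test_bucket_assignment(self):
        markers = self.make_markers({"gA": {1, 2, 6}, "gB": {1, 7}, "gC": {2}, "gD": set()})
        bd = intersect_targets_with_markers(["gA", "gB", "gC", "gD"], markers)
        assert bd.bucket_3plus == {"gA"}
        assert bd.bucket_2 == {"gB"}
        assert bd.bucket_1 == {"gC"}
        assert "gD" not in bd.candidates

    def test_non_target_markers_ignored(self):
        markers = self.make_markers({"gA": {1, 2}, "gZ": {1, 2, 6, 7}})
        bd = intersect_targets_with_markers(["gA"], markers)
        assert bd.candidates == {"gA"}

    def test_marker_outside_lkc_clusters_not_counted(self):
        markers = self.make_markers({"gA": {0, 3}})  # marker only in non-lKC clusters
        bd = intersect_targets_with_markers(["gA"], markers)
        assert not bd.candidates

    def test_partition_property(self, rng):
        membership = {
            f"g{i}": set(rng.choice([1, 2, 6, 7], size=rng.integers(0, 5), replace=False).tolist())
            for i in range(40)
        }
        markers = self.make_markers(membership)
        bd = intersect_targets_with_markers(list(membership), markers)
        assert sum(bd.bucket_sizes.values()) == len(bd.candidates)
        planted = {g for g, cl in membership.items() if cl}
        assert bd.candidates == planted

    def test_planted_bucket_recovery(self, rng):
        membership = {}
        for i in range(4):
            membership[f"b3_{i}"] = set(rng.choice([1, 2, 6, 7], size=3, replace=False).tolist())
        for i in range(10):
            membership[f"b2_{i}"] = set(rng.choice([1, 2, 6, 7], size=2, replace=False).tolist())
        for i in range(20):
            membership[f"b1_{i}"] = {int(rng.choice([1, 2, 6, 7]))}
        bd = intersect_targets_with_markers(
            list(membership), self.make_markers(membership)
        )
        assert bd.bucket_sizes == {"3+": 4, "2": 10, "1": 20}

    def test_depleted_gene_is_not_a_candidate(self):
        markers = self.make_markers({"gA": {1}})
        markers.loc[(markers["gene_id"] == "gA") & (markers["cluster"] == 1), "effect"] = -2.0
        assert not intersect_targets_with_markers(["gA"], markers).candidates
        both = intersect_targets_with_markers(["gA"], markers, positive_only=False)
        assert both.candidates == {"gA"}

    def test_unknown_cluster_rejected(self):
        markers = self.make_markers({"gA": {1}})
        with pytest.raises(ValueError):
            intersect_targets_with_markers(["gA"], markers, lkc_clusters={1, 2, 6, 42})


class TestReciprocalBestHits:
    def hits(self, rows):
        return pd.DataFrame(rows, columns=["qseqid", "sseqid", "bitscore", "evalue"])

    def test_simple_pair(self):
        a2b = self.hits([("a1", "b1", 200.0, 1e-50)])
        b2a = self.hits([("b1", "a1", 190.0, 1e-48)])
        out = reciprocal_best_hits(a2b, b2a)
        assert out[["id_a", "id_b"]].values.tolist() == [["a1", "b1"]]
        assert out.iloc[0]["score_a2b"] == 200.0

    def test_one_sided_best_is_no_pair(self):
        a2b = self.hits([("a1", "b1", 200.0, 1e-50)])
        b2a = self.hits([("b1", "a2", 300.0, 1e-60), ("b1", "a1", 190.0, 1e-48)])
        assert reciprocal_best_hits(a2b, b2a).empty

    def test_tie_break_bitscore_evalue_lexicographic(self):
        a2b = self.hits([("a1", "b2", 200.0, 1e-50), ("a1", "b1", 200.0, 1e-50)])
        b2a = self.hits([("b1", "a1", 180.0, 1e-40), ("b2", "a1", 180.0, 1e-40)])
        out = reciprocal_best_hits(a2b, b2a)
        # equal score and e-value: lexicographically smaller subject wins
        assert out[["id_a", "id_b"]].values.tolist() == [["a1", "b1"]]

    def test_duplicate_rows_keep_best_with_warning(self):
        a2b = self.hits([("a1", "b1", 100.0, 1e-10), ("a1", "b1", 200.0, 1e-50)])
        b2a = self.hits([("b1", "a1", 150.0, 1e-30)])
        with pytest.warns(UserWarning, match="duplicate"):
            out = reciprocal_best_hits(a2b, b2a)
        assert out.iloc[0]["score_a2b"] == 200.0

    def test_symmetry_of_roles(self):
        a2b, b2a, _ = generate_hit_tables(20, 25, 8, seed=3)
        fwd = reciprocal_best_hits(a2b, b2a)
        rev = reciprocal_best_hits(b2a, a2b)
        assert {(a, b) for a, b in fwd[["id_a", "id_b"]].values} == {
            (a, b) for b, a in rev[["id_a", "id_b"]].values
        }

    def test_random_tables_match_definition_oracle(self, rng):
        seed = int(rng.integers(2**31))
        a2b, b2a, _ = generate_hit_tables(30, 30, 10, seed=seed, decoys_per_query=5)
        got = {(a, b) for a, b in reciprocal_best_hits(a2b, b2a)[["id_a", "id_b"]].values}
        assert got == rbh_by_definition(a2b, b2a)
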
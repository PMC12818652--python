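import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from altdonor import (
    GeneSetCollection,
    RankedGeneList,
    correlate_genes,
    enrichment_score,
    filter_gene_sets,
    gsea_preranked,
    read_gmt,
)
from altdonor.enrichment import gaf_to_gmt, read_ranked_list, write_gmt, write_ranked_list

from _oracles import ks_statistic_on_ranks


@pytest.fixture
def ranked_linear():
    """100 genes with scores descending 1.0 ... -0.98."""
    entries = [(f"g{i:03d}", 1.0 - 0.02 * i) for i in range(100)]
    return RankedGeneList(entries=entries)


class TestCorrelation:
    def test_perfect_linear_relation(self):
        inex = pd.Series([0.1, 0.5, -0.3, 0.9], index=list("abcd"))
        expr = pd.DataFrame({"gene1": 2 * inex + 5}, index=list("abcd"))
        ranked = correlate_genes(expr, inex)
        assert dict(ranked.entries)["gene1"] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        inex = pd.Series([0.1, 0.5, -0.3, 0.9], index=list("abcd"))
        expr = pd.DataFrame({"gene1": -inex}, index=list("abcd"))
        assert dict(correlate_genes(expr, inex).entries)["gene1"] == pytest.approx(-1.0)

    def test_constant_gene_flagged_with_zero_score(self):
        inex = pd.Series([0.1, 0.5, -0.3], index=list("abc"))
        expr = pd.DataFrame({"flat": [7.0, 7.0, 7.0]}, index=list("abc"))
        ranked = correlate_genes(expr, inex)
        assert dict(ranked.entries)["flat"] == 0.0
        assert "flat" in ranked.flagged

    def test_too_few_overlapping_samples(self):
        inex = pd.Series([0.1, 0.5], index=list("ab"))
        expr = pd.DataFrame({"g": [1.0, 2.0]}, index=list("ab"))
        with pytest.raises(ValueError, match="overlapping samples"):
            correlate_genes(expr, inex)

    def test_sorted_descending_with_deterministic_ties(self):
        ranked = RankedGeneList(entries=[("b", 0.5), ("a", 0.5), ("c", 0.9)])
        assert ranked.genes == ["c", "a", "b"]

    def test_matches_scipy_pearson(self, rng):
        inex = pd.Series(rng.normal(size=20), index=[f"s{i}" for i in range(20)])
        expr = pd.DataFrame(
            rng.normal(size=(20, 5)), index=inex.index, columns=[f"g{i}" for i in range(5)]
        )
        ranked = dict(correlate_genes(expr, inex).entries)
        for g in expr.columns:
            assert ranked[g] == pytest.approx(sps.pearsonr(expr[g], inex)[0], abs=1e-12)


class TestSetFilter:
    def make_collection(self, sizes):
        return GeneSetCollection(sets={f"set{n}": [f"g{i:03d}" for i in range(n)] for n in sizes})

    def test_size_boundaries_inclusive(self, ranked_linear):
        coll = self.make_collection([19, 20, 50])
        kept = filter_gene_sets(coll, ranked_linear, min_size=20, max_size=500)
        assert set(kept.sets) == {"set20", "set50"}

    def test_overlap_with_universe_counts_not_raw_size(self, ranked_linear):
        # 30 members but only 10 in the ranked universe
        coll = GeneSetCollection(
            sets={"mostly_outside": [f"g{i:03d}" for i in range(10)] + [f"x{i}" for i in range(20)]}
        )
        assert len(filter_gene_sets(coll, ranked_linear, min_size=20, max_size=500)) == 0

    def test_max_size_dropped(self):
        entries = [(f"g{i:04d}", 1.0 - i * 1e-3) for i in range(600)]
        ranked = RankedGeneList(entries=entries)
        coll = GeneSetCollection(sets={"huge": [f"g{i:04d}" for i in range(501)]})
        assert len(filter_gene_sets(coll, ranked, min_size=20, max_size=500)) == 0


class TestEnrichmentScore:
    def test_singleton_top_gene_reaches_one(self, ranked_linear):
        es, running = enrichment_score(ranked_linear, {"g000"})
        assert es == pytest.approx(1.0)
        assert running[0] == pytest.approx(1.0)

    def test_bottom_tail_set_is_negative(self, ranked_linear):
        members = {f"g{i:03d}" for i in range(90, 100)}
        es, _ = enrichment_score(ranked_linear, members)
        assert es < 0

    def test_matches_brute_force_running_sum(self, ranked_linear, rng):
        scores = ranked_linear.scores
        genes = ranked_linear.genes
        for _ in range(25):
            members = set(rng.choice(genes, size=int(rng.integers(2, 30)), replace=False))
            es, running = enrichment_score(ranked_linear, members)
            # direct recomputation over all positions
            norm = sum(abs(s) for g, s in ranked_linear.entries if g in members)
            acc, best = 0.0, 0.0
            for g, s in ranked_linear.entries:
                acc += abs(s) / norm if g in members else -1.0 / (len(genes) - len(members))
                if abs(acc) > abs(best):
                    best = acc
            assert es == pytest.approx(best, abs=1e-12)

    def test_weight_zero_reduces_to_ks_on_ranks(self, ranked_linear, rng):
        genes = ranked_linear.genes
        for _ in range(10):
            members = set(rng.choice(genes, size=10, replace=False))
            es, _ = enrichment_score(ranked_linear, members, weight_p=0.0)
            positions = {i for i, g in enumerate(genes) if g in members}
            assert es == pytest.approx(ks_statistic_on_ranks(len(genes), positions), abs=1e-12)

    def test_reversed_list_negates_es(self, ranked_linear, rng):
        members = set(rng.choice(ranked_linear.genes, size=12, replace=False))
        es_fwd, _ = enrichment_score(ranked_linear, members)
        reversed_entries = [(g, -s) for g, s in ranked_linear.entries]
        es_rev, _ = enrichment_score(RankedGeneList(entries=reversed_entries), members)
        assert es_rev == pytest.approx(-es_fwd, abs=1e-12)

    def test_no_member_in_list_is_an_error(self, ranked_linear):
        with pytest.raises(ValueError, match="no gene-set member"):
            enrichment_score(ranked_linear, {"absent"})


class TestGseaPreranked:
    def test_top_decile_set_maximally_enriched(self, ranked_linear):
        coll = GeneSetCollection(sets={"top": [f"g{i:03d}" for i in range(10)]})
        res = gsea_preranked(ranked_linear, coll, n_perm=200, seed=7)[0]
        assert res.nes > 0
        assert res.p_value <= 1.0 / (200 + 1) + 1e-12

    def test_same_seed_is_bitwise_identical(self, ranked_linear):
        coll = GeneSetCollection(
            sets={"a": [f"g{i:03d}" for i in range(0, 25)],
                  "b": [f"g{i:03d}" for i in range(40, 70)]}
        )
        r1 = gsea_preranked(ranked_linear, coll, n_perm=100, seed=1111)
        r2 = gsea_preranked(ranked_linear, coll, n_perm=100, seed=1111)
        assert r1 == r2

    def test_sign_consistency_and_bh_monotonicity(self, ranked_linear, rng):
        sets = {
            f"rand{k}": list(rng.choice(ranked_linear.genes, size=15, replace=False))
            for k in range(8)
        }
        res = gsea_preranked(ranked_linear, GeneSetCollection(sets=sets), n_perm=150, seed=3)
        for r in res:
            assert np.sign(r.nes) == np.sign(r.es)
            assert r.p_adjusted >= r.p_value - 1e-15
        ordered = sorted(res, key=lambda r: r.p_value)
        adj = [r.p_adjusted for r in ordered]
        assert all(a <= b + 1e-12 for a, b in zip(adj, adj[1:]))

    def test_null_sets_give_uniform_p(self, rng):
        # sets drawn uniformly from the universe: permutation p ~ Uniform(0,1)
        entries = [(f"g{i:03d}", float(s)) for i, s in enumerate(np.sort(rng.normal(size=150))[::-1])]
        ranked = RankedGeneList(entries=entries)
        pvals = []
        for rep in range(200):
            members = list(rng.choice(ranked.genes, size=15, replace=False))
            res = gsea_preranked(ranked, GeneSetCollection(sets={"s": members}),
                                 n_perm=500, seed=int(rng.integers(2**31)))
            pvals.append(res[0].p_value)
        ks = sps.kstest(pvals, "uniform")
        assert ks.pvalue > 1e-3


class TestEnrichmentIO:
    def test_gmt_roundtrip(self, tmp_path):
        coll = GeneSetCollection(
            sets={"s1": ["a", "b", "c"], "s2": ["d", "e"]},
            descriptions={"s1": "first", "s2": "second"},
        )
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.sets == coll.sets
        assert back.descriptions == coll.descriptions

    def test_gmt_deduplicates_members(self):
        coll = GeneSetCollection(sets={"s": ["a", "b", "a"]})
        assert coll.sets["s"] == ["a", "b"]

    def test_gaf_conversion(self, tmp_path):
        gaf = tmp_path / "anno.gaf"
        gaf.write_text(
            "!gaf-version: 2.2\n"
            "DB\tID1\tGENE1\t\tGO:0001\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t\t\n"
            "DB\tID2\tGENE2\t\tGO:0001\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t\t\n"
            "DB\tID3\tGENE3\t\tGO:0002\tREF\tIEA\t\tP\t\t\tprotein\ttaxon:9606\t\t\n"
        )
        coll = gaf_to_gmt(gaf, tmp_path / "anno.gmt")
        assert coll.sets["GO:0001"] == ["GENE1", "GENE2"]
        assert read_gmt(tmp_path / "anno.gmt").sets == coll.sets

    def test_ranked_list_roundtrip(self, tmp_path, ranked_linear):
        path = tmp_path / "ranked.tsv"
        write_ranked_list(ranked_linear, path)
        back = read_ranked_list(path)
        assert back.entries == ranked_linear.entries
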
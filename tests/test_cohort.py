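import itertools

import numpy as np
import pytest
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from altdonor import (
    CohortTable,
    DistanceMatrix,
    SampleRecord,
    complete_linkage_cluster,
    distance_matrix,
    filter_samples,
    tissue_distribution,
    wasserstein1d,
    wilcoxon_ranksum,
)
from altdonor.cohort import is_cns_category, read_s1_table, read_sample_table

from _oracles import enumerate_ranksum_p, lp_wasserstein


def make_record(sample_id="s", tissue="liver", cns=False, inc=5, exc=5, tpm=10.0):
    return SampleRecord(
        sample_id=sample_id,
        tissue_type=tissue,
        tissue_category=tissue,
        is_cns=cns,
        inclusion_reads=inc,
        exclusion_reads=exc,
        gene_tpm=tpm,
    )


def cohort_from_ratios(groups: dict[str, list[float]], cns: set[str] = frozenset()) -> CohortTable:
    """Build a cohort whose per-group ratios approximate the given values."""
    records = []
    for tissue, ratios in groups.items():
        for i, r in enumerate(ratios):
            # choose counts with inc+exc = 1000 giving ratio within 1/1000
            inc = round((r + 1) / 2 * 1000)
            records.append(
                make_record(f"{tissue}_{i}", tissue, tissue in cns, inc, 1000 - inc, 10.0)
            )
    return filter_samples(records)


class TestFilter:
    def test_low_tpm_excluded(self):
        assert len(filter_samples([make_record(tpm=0.5, inc=10, exc=10)])) == 0

    def test_low_coverage_excluded(self):
        assert len(filter_samples([make_record(tpm=2.0, inc=2, exc=0)])) == 0

    def test_boundary_inclusive(self):
        cohort = filter_samples([make_record(tpm=1.0, inc=2, exc=1)])
        assert len(cohort) == 1

    def test_idempotent(self, rng):
        records = [
            make_record(f"s{i}", tpm=float(rng.uniform(0, 3)),
                        inc=int(rng.integers(0, 5)), exc=int(rng.integers(0, 5)))
            for i in range(100)
        ]
        once = filter_samples(records)
        twice = filter_samples(once.records)
        assert once.records == twice.records

    def test_reports_retained_per_tissue(self):
        cohort = filter_samples(
            [make_record("a", "brain"), make_record("b", "brain"), make_record("c", "liver")]
        )
        assert cohort.retained_per_tissue == {"brain": 2, "liver": 1}

    def test_cns_lookup(self):
        assert is_cns_category("Forebrain")
        assert is_cns_category("spinal cord")
        assert not is_cns_category("liver")
        assert is_cns_category("liver", cns_categories={"liver"})  # overridable


class TestTissueDistribution:
    def test_degenerate_distribution_single_bin(self):
        cohort = filter_samples([make_record(f"s{i}", inc=10, exc=0) for i in range(4)])
        hists = tissue_distribution(cohort)
        dens = hists["liver"]["density"]
        assert (dens > 0).sum() == 1
        assert hists["liver"]["n"] == 4

    def test_separated_groups_occupy_disjoint_bins(self):
        cohort = cohort_from_ratios({"brain": [1, 1], "liver": [-1, -1]}, cns={"brain"})
        hists = tissue_distribution(cohort, group_by="cns_flag")
        occupied = {k: set(np.nonzero(v["density"])[0]) for k, v in hists.items()}
        assert occupied["CNS"].isdisjoint(occupied["other"])

    def test_unit_area_normalization(self, rng):
        ratios = list(rng.uniform(-1, 1, size=37))
        cohort = cohort_from_ratios({"liver": ratios})
        hists = tissue_distribution(cohort, bin_width=0.1)
        area = (hists["liver"]["density"] * np.diff(hists["liver"]["edges"])).sum()
        assert area == pytest.approx(1.0, abs=1e-12)


class TestWasserstein:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([0, 1], [0, 1], 0.0),
            ([0], [3], 3.0),
            ([0, 2], [1, 3], 1.0),  # matches the transport LP on the 2x2 coupling
        ],
    )
    def test_examples(self, x, y, expected):
        assert wasserstein1d(x, y) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_lp_transport_oracle(self, rng):
        for _ in range(60):
            x = rng.normal(size=int(rng.integers(1, 7)))
            y = rng.normal(size=int(rng.integers(1, 7)))
            assert wasserstein1d(x, y) == pytest.approx(lp_wasserstein(x, y), abs=1e-9)

    def test_agrees_with_scipy_on_unequal_sizes(self, rng):
        for _ in range(30):
            x = rng.uniform(-1, 1, size=int(rng.integers(2, 40)))
            y = rng.uniform(-1, 1, size=int(rng.integers(2, 40)))
            assert wasserstein1d(x, y) == pytest.approx(
                sps.wasserstein_distance(x, y), abs=1e-12
            )

    def test_translation_invariance(self, rng):
        x = rng.normal(size=11)
        y = rng.normal(size=7)
        assert wasserstein1d(x + 3.7, y + 3.7) == pytest.approx(wasserstein1d(x, y), abs=1e-12)

    def test_higher_order_p_on_point_masses(self):
        # W_p between point masses is the distance for every p
        assert wasserstein1d([0.0], [3.0], p=2) == pytest.approx(3.0, abs=1e-12)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            wasserstein1d([], [1.0])


class TestDistanceMatrix:
    def test_identical_groups_have_zero_distance(self):
        cohort = cohort_from_ratios({"a": [0.5, -0.5], "b": [0.5, -0.5]})
        dm = distance_matrix(cohort)
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_maximal_separation_is_two(self):
        cohort = cohort_from_ratios({"a": [-1, -1, -1], "b": [1, 1, 1]})
        dm = distance_matrix(cohort)
        assert dm.values[0, 1] == pytest.approx(2.0, abs=1e-9)

    def test_matches_pairwise_calls_and_triangle_inequality(self, rng):
        groups = {k: list(rng.uniform(-1, 1, size=8)) for k in "abc"}
        cohort = cohort_from_ratios(groups)
        dm = distance_matrix(cohort)
        ratios = cohort.groups()
        for (i, a), (j, b) in itertools.combinations(enumerate(dm.labels), 2):
            assert dm.values[i, j] == pytest.approx(
                wasserstein1d(ratios[a], ratios[b]), abs=1e-12
            )
        for i, j, k in itertools.permutations(range(3), 3):
            assert dm.values[i, j] <= dm.values[i, k] + dm.values[k, j] + 1e-9

    def test_single_group_is_an_error(self):
        cohort = cohort_from_ratios({"a": [0.1, 0.2]})
        with pytest.raises(ValueError, match="two groups"):
            distance_matrix(cohort)


class TestCompleteLinkage:
    def test_hand_traced_merges(self):
        dm = DistanceMatrix(labels=["A", "B", "C"],
                            values=np.array([[0, 1, 5], [1, 0, 6], [5, 6, 0.0]]))
        dendro = complete_linkage_cluster(dm)
        (l1, r1, h1), (l2, r2, h2) = dendro.merges
        assert {l1, r1} == {("A",), ("B",)} and h1 == 1
        assert h2 == 6  # complete linkage: max(d(A,C), d(B,C))

    def test_equal_distances_tie_break_by_label(self):
        vals = np.full((3, 3), 2.0)
        np.fill_diagonal(vals, 0.0)
        dendro = complete_linkage_cluster(DistanceMatrix(labels=["z", "y", "x"], values=vals))
        first = dendro.merges[0]
        assert {first[0], first[1]} == {("x",), ("y",)}
        assert all(h == 2.0 for *_, h in dendro.merges)

    def test_two_labels(self):
        dm = DistanceMatrix(labels=["A", "B"], values=np.array([[0, 0.7], [0.7, 0.0]]))
        dendro = complete_linkage_cluster(dm)
        assert dendro.merges == [(("A",), ("B",), 0.7)]
        assert dendro.to_newick().endswith(";")

    def test_heights_match_scipy_complete_linkage(self, rng):
        n = 7
        pts = rng.normal(size=(n, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(labels=[f"t{i}" for i in range(n)], values=d)
        ours = sorted(h for *_, h in complete_linkage_cluster(dm).merges)
        scipys = sorted(linkage(squareform(d), method="complete")[:, 2])
        assert ours == pytest.approx(scipys, abs=1e-9)

    def test_merge_heights_non_decreasing(self, rng):
        n = 9
        d = np.abs(rng.normal(size=(n, n)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        # complete linkage is monotone for any dissimilarity
        heights = [h for *_, h in complete_linkage_cluster(
            DistanceMatrix(labels=[f"t{i}" for i in range(n)], values=d)).merges]
        assert all(a <= b + 1e-12 for a, b in zip(heights, heights[1:]))


class TestWilcoxon:
    def test_fully_separated_small_samples(self):
        res = wilcoxon_ranksum([1, 2, 3], [4, 5, 6], mode="exact")
        # 2 of the 20 rank assignments are as extreme as observed
        assert res.p_value == pytest.approx(0.1, abs=1e-12)
        assert res.effect_size_r == pytest.approx(abs(res.z_statistic) / np.sqrt(6), abs=1e-12)

    def test_identical_samples(self):
        res = wilcoxon_ranksum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.z_statistic == 0.0
        assert res.effect_size_r == 0.0

    def test_all_values_tied_degenerate(self):
        res = wilcoxon_ranksum([5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p_value == 1.0
        assert res.effect_size_r == 0.0

    def test_exact_matches_full_enumeration_with_ties(self, rng):
        for _ in range(40):
            n_x = int(rng.integers(2, 7))
            n_y = int(rng.integers(2, 13 - n_x))
            # coarse values force ties
            x = rng.integers(0, 4, size=n_x).astype(float)
            y = rng.integers(0, 4, size=n_y).astype(float)
            res = wilcoxon_ranksum(x, y, mode="exact")
            assert res.p_value == pytest.approx(enumerate_ranksum_p(x, y), abs=1e-9)

    def test_normal_approx_matches_tie_corrected_mannwhitney(self, rng):
        x = rng.integers(0, 10, size=40).astype(float)
        y = rng.integers(2, 12, size=35).astype(float)
        res = wilcoxon_ranksum(x, y, mode="normal_approx")
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                               use_continuity=False)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_auto_switches_to_normal_for_large_samples(self, rng):
        x = rng.normal(size=150)
        y = rng.normal(size=120)
        res = wilcoxon_ranksum(x, y, mode="auto")
        assert res.method == "normal_approx"

    def test_effect_size_invariant_under_monotone_transform(self, rng):
        x = rng.uniform(0.1, 1, size=12)
        y = rng.uniform(0.2, 1.1, size=9)
        r1 = wilcoxon_ranksum(x, y).effect_size_r
        r2 = wilcoxon_ranksum(np.log(x), np.log(y)).effect_size_r
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestCohortIO:
    def test_sample_table_roundtrip(self, tmp_path):
        path = tmp_path / "samples.tsv"
        path.write_text(
            "sample_id\ttissue_type\ttissue_category\tinclusion_reads\texclusion_reads\tgene_tpm\n"
            "s1\tcortex\tbrain\t8\t2\t5.5\n"
            "s2\tliver\tliver\t1\t9\t2.0\n"
        )
        recs = read_sample_table(path)
        assert recs[0].is_cns and not recs[1].is_cns
        assert recs[0].inex_ratio == pytest.approx(0.6)

    def test_missing_column_is_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\ttissue_type\n" "s1\tliver\n")
        with pytest.raises(ValueError, match="tissue_category"):
            read_sample_table(path)

    def test_s1_style_column_synonyms(self, tmp_path):
        path = tmp_path / "s1.tsv"
        path.write_text(
            "Sample\tTissue type\tTissue category\tGNNK+\tGNNK-\tTPM\n"
            "h1\tcortex\tbrain\t9\t1\t4.0\n"
        )
        recs = read_s1_table(path)
        assert recs[0].inclusion_reads == 9
        assert recs[0].is_cns
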
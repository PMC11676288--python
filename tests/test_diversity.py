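"""Alpha indices against closed forms, PCoA/PERMANOVA against independent
oracles (including scikit-bio), and rank-level group comparisons."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from benthicom import (
    CommunityTable,
    PairwiseMatrix,
    SampleMetadata,
    alpha_diversity,
    bray_curtis,
    group_compare_rank,
    pcoa,
    permanova,
    rank_sum_test,
)


def _table(rows, samples=None, taxa=None):
    rows = np.atleast_2d(rows)
    samples = samples or [f"S{i}" for i in range(rows.shape[0])]
    taxa = taxa or [f"t{j}" for j in range(rows.shape[1])]
    return CommunityTable(pd.DataFrame(rows, index=samples, columns=taxa))


class TestAlpha:
    def test_uniform_four_taxa(self):
        res = alpha_diversity(_table([[10, 10, 10, 10]]))
        assert res["shannon"].iloc[0] == pytest.approx(math.log(4), abs=1e-10)
        assert res["simpson"].iloc[0] == pytest.approx(0.75, abs=1e-10)
        assert res["pielou"].iloc[0] == pytest.approx(1.0, abs=1e-10)

    def test_chao1_with_singletons_and_doubletons(self):
        res = alpha_diversity(_table([[5, 3, 2, 1, 1]]))
        # S=5, F1=2, F2=1 -> 5 + 2*1/(2*2) = 5.5
        assert res["chao1"].iloc[0] == pytest.approx(5.5, abs=1e-10)

    def test_chao1_without_doubletons(self):
        res = alpha_diversity(_table([[5, 3, 1, 1]]))
        # S=4, F1=2, F2=0 -> 4 + 2*1/2 = 5
        assert res["chao1"].iloc[0] == pytest.approx(5.0, abs=1e-10)

    def test_single_taxon_sample(self):
        res = alpha_diversity(_table([[7]]))
        assert res["shannon"].iloc[0] == 0.0
        assert res["simpson"].iloc[0] == 0.0
        assert res["chao1"].iloc[0] == 1.0
        assert np.isnan(res["pielou"].iloc[0])
        assert not res["pielou_defined"].iloc[0]

    def test_matches_formula_reimplementation(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.integers(0, 30, size=12)
            if x.sum() == 0 or (x > 0).sum() < 2:
                continue
            res = alpha_diversity(_table([x]))
            p = x[x > 0] / x.sum()
            assert res["shannon"].iloc[0] == pytest.approx(
                -(p * np.log(p)).sum(), abs=1e-10)
            assert res["simpson"].iloc[0] == pytest.approx(
                1 - (p ** 2).sum(), abs=1e-10)
            f1, f2 = (x == 1).sum(), (x == 2).sum()
            assert res["chao1"].iloc[0] == pytest.approx(
                (x > 0).sum() + f1 * (f1 - 1) / (2 * (f2 + 1)), abs=1e-10)

    def test_chao1_at_least_observed_richness(self):
        rng = np.random.default_rng(1)
        t = _table(rng.integers(0, 5, size=(10, 40)) + (rng.random((10, 40)) < 0.1))
        res = alpha_diversity(t)
        assert (res["chao1"] >= res["richness"] - 1e-12).all()


class TestBrayCurtis:
    def test_identical_samples_are_zero(self):
        d = bray_curtis(_table([[3, 4], [3, 4]]))
        assert d.values.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_samples_are_one(self):
        d = bray_curtis(_table([[5, 0], [0, 9]]))
        assert d.values.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_computed_value(self):
        d = bray_curtis(_table([[10, 0], [5, 5]]))
        assert d.values.iloc[0, 1] == pytest.approx(0.5)

    def test_unweighted_uses_presence_absence(self):
        d = bray_curtis(_table([[10, 1, 0], [1, 10, 0]]), weighted=False)
        assert d.values.iloc[0, 1] == pytest.approx(0.0)


class TestPcoa:
    def test_points_on_a_line_recovered(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(x[:, None] - x[None, :])
        dist = PairwiseMatrix(pd.DataFrame(
            d, index=list("abcd"), columns=list("abcd")))
        res = pcoa(dist)
        assert res.proportion_explained[0] == pytest.approx(1.0, abs=1e-8)
        axis1 = res.coordinates.iloc[:, 0].to_numpy()
        gaps = np.diff(axis1)
        np.testing.assert_allclose(np.abs(gaps), np.diff(x), atol=1e-8)

    def test_gower_identity_for_euclidean_input(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(7, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dist = PairwiseMatrix(pd.DataFrame(
            d, index=[f"s{i}" for i in range(7)],
            columns=[f"s{i}" for i in range(7)]))
        res = pcoa(dist)
        coords = res.coordinates.to_numpy()
        recon = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.testing.assert_allclose(recon, d, atol=1e-8)

    def test_duplicate_samples_get_identical_coordinates(self):
        t = _table([[5, 1, 0], [5, 1, 0], [0, 3, 3]])
        res = pcoa(bray_curtis(t))
        np.testing.assert_allclose(res.coordinates.iloc[0].to_numpy(),
                                   res.coordinates.iloc[1].to_numpy(),
                                   atol=1e-10)

    def test_matches_skbio_eigenvalues(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        t = _table(rng.integers(1, 50, size=(9, 15)))
        dist = bray_curtis(t)
        ours = pcoa(dist)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dist.values.to_numpy(), ids=dist.sample_ids))
        k = len(ours.eigenvalues)
        np.testing.assert_allclose(
            ours.eigenvalues, theirs.eigvals.to_numpy()[:k], atol=1e-8)

    def test_invariant_to_sample_ordering(self):
        rng = np.random.default_rng(4)
        t = _table(rng.integers(1, 50, size=(8, 10)))
        dist = bray_curtis(t)
        res = pcoa(dist)
        perm = rng.permutation(8)
        ids = [dist.sample_ids[i] for i in perm]
        shuffled = PairwiseMatrix(dist.values.loc[ids, ids])
        res2 = pcoa(shuffled)
        a = res.coordinates.loc[ids].to_numpy()
        b = res2.coordinates.to_numpy()
        for k in range(a.shape[1]):  # equality up to the per-axis sign choice
            assert (np.allclose(a[:, k], b[:, k], atol=1e-8)
                    or np.allclose(a[:, k], -b[:, k], atol=1e-8))


def _brute_force_permanova_f(d2, labels):
    labels = np.asarray(labels)
    n = len(labels)
    groups = np.unique(labels)
    ss_t = d2[np.triu_indices(n, 1)].sum() / n
    ss_w = 0.0
    for g in groups:
        idx = np.nonzero(labels == g)[0]
        for i, j in combinations(idx, 2):
            ss_w += d2[i, j]
    ss_w_scaled = 0.0
    for g in groups:
        idx = np.nonzero(labels == g)[0]
        s = sum(d2[i, j] for i, j in combinations(idx, 2))
        ss_w_scaled += s / len(idx)
    ss_a = ss_t - ss_w_scaled
    a = len(groups)
    return (ss_a / (a - 1)) / (ss_w_scaled / (n - a))


class TestPermanova:
    def test_label_symmetry(self):
        rng = np.random.default_rng(5)
        t = _table(rng.integers(1, 40, size=(8, 12)))
        d = bray_curtis(t)
        g1 = pd.Series(list("AAAABBBB"), index=t.sample_ids)
        g2 = pd.Series(list("BBBBAAAA"), index=t.sample_ids)
        assert permanova(d, g1, 99, 0).f_statistic == pytest.approx(
            permanova(d, g2, 99, 0).f_statistic)

    def test_separated_groups_reach_minimum_p(self):
        block = np.zeros((12, 12))
        block[:6, 6:] = 10.0
        block[6:, :6] = 10.0
        block[:6, :6] = 0.1
        block[6:, 6:] = 0.1
        np.fill_diagonal(block, 0.0)
        ids = [f"s{i}" for i in range(12)]
        d = PairwiseMatrix(pd.DataFrame(block, index=ids, columns=ids))
        g = pd.Series(["A"] * 6 + ["B"] * 6, index=ids)
        res = permanova(d, g, 999, seed=0)
        # only permutations reproducing the planted split (prob 2/924 each)
        # can match F_obs, so p sits at the floor of the add-one rule
        assert res.p_value <= 5 / 1000

    def test_f_matches_exhaustive_enumeration_on_four_samples(self):
        rng = np.random.default_rng(6)
        t = _table(rng.integers(1, 30, size=(4, 6)))
        d = bray_curtis(t)
        d2 = d.values.to_numpy() ** 2
        g = pd.Series(["A", "A", "B", "B"], index=t.sample_ids)
        ours = permanova(d, g, 99, 0).f_statistic
        # the three distinct 2|2 splits form the whole permutation space
        splits = [["A", "A", "B", "B"], ["A", "B", "A", "B"],
                  ["A", "B", "B", "A"]]
        fs = [_brute_force_permanova_f(d2, s) for s in splits]
        assert ours == pytest.approx(fs[0], abs=1e-10)
        assert min(fs) <= ours <= max(fs)

    def test_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        t = _table(rng.integers(1, 40, size=(10, 12)))
        d = bray_curtis(t)
        g = ["A"] * 5 + ["B"] * 5
        ours = permanova(d, pd.Series(g, index=t.sample_ids), 99, 0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(d.values.to_numpy(), ids=d.sample_ids),
            grouping=g, permutations=0)
        assert ours.f_statistic == pytest.approx(theirs["test statistic"],
                                                 abs=1e-10)


class TestGroupCompare:
    def test_identical_groups_give_p_one(self, taxonomy):
        data = np.tile([[10, 5, 2]], (12, 1))
        t = CommunityTable(pd.DataFrame(
            data, index=[f"S{i}" for i in range(12)],
            columns=["ASV_1", "ASV_2", "ASV_3"]))
        md = SampleMetadata(frame=pd.DataFrame(
            {"group": ["BG"] * 6 + ["CG"] * 6}, index=t.sample_ids))
        res = group_compare_rank(t, taxonomy, md)
        np.testing.assert_allclose(res["p_value"].to_numpy(), 1.0)

    def test_complete_separation_exact_p(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [7, 8, 9, 10, 11, 12]
        _, p = rank_sum_test(x, y)
        expected = 2 * (math.factorial(6) ** 2) / math.factorial(12)
        assert p == pytest.approx(expected, rel=1e-9)

    def test_invariant_to_sample_order(self, taxonomy):
        rng = np.random.default_rng(8)
        data = pd.DataFrame(
            rng.integers(1, 100, size=(12, 3)),
            index=[f"S{i}" for i in range(12)],
            columns=["ASV_1", "ASV_2", "ASV_3"])
        md_frame = pd.DataFrame({"group": ["BG"] * 6 + ["CG"] * 6},
                                index=data.index)
        t1 = CommunityTable(data)
        res1 = group_compare_rank(t1, taxonomy, SampleMetadata(md_frame))
        perm = rng.permutation(12)
        t2 = CommunityTable(data.iloc[perm])
        res2 = group_compare_rank(t2, taxonomy, SampleMetadata(md_frame))
        pd.testing.assert_series_equal(
            res1["p_value"].sort_index(), res2["p_value"].sort_index())
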
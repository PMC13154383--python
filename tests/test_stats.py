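import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr

from halovir import stats as st
from halovir.io import load_field_metadata


def dist_df(points):
    d = squareform(pdist(np.asarray(points, dtype=float)))
    return pd.DataFrame(d)


class TestDiversity:
    def test_uniform_community(self):
        r = st.diversity([5.0] * 10)
        assert r.shannon == pytest.approx(math.log(10))
        assert r.pielou == pytest.approx(1.0)
        assert r.richness == 10

    def test_chao1_equals_richness_without_singletons(self):
        r = st.diversity([3, 4, 5, 2, 2])
        assert r.chao1 == pytest.approx(r.richness)

    def test_single_taxon_zero_entropy(self):
        assert st.diversity([7]).shannon == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            st.diversity([0, 0, 0])

    def test_matches_reference_implementation(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.diversity.alpha import chao1, pielou_e, shannon
        counts = rng.integers(0, 30, size=40)
        counts[0] = 1  # ensure a singleton
        r = st.diversity(counts)
        assert r.shannon == pytest.approx(shannon(counts, base=math.e))
        assert r.pielou == pytest.approx(pielou_e(counts))
        assert r.chao1 == pytest.approx(chao1(counts))


class TestClr:
    def test_equal_row_maps_to_zero(self):
        out = st.clr(pd.DataFrame([[3.0, 3.0, 3.0]]))
        assert np.allclose(out.values, 0)

    def test_rows_sum_to_zero(self, rng):
        x = rng.random((5, 8))
        assert np.allclose(st.clr(x).sum(axis=1), 0, atol=1e-10)

    def test_scale_invariance_on_positive_data(self, rng):
        x = rng.random((4, 6)) + 0.1
        a = st.clr(x, pseudocount=0.0)
        b = st.clr(x * 100.0, pseudocount=0.0)
        assert np.allclose(a.values, b.values)


class TestNmds:
    def test_planar_distances_embed_near_perfectly(self, rng):
        pts = rng.random((10, 2))
        out = st.nmds(dist_df(pts), restarts=5, seed=0)
        assert out.stress < 0.01

    def test_three_points_always_embed(self):
        d = pd.DataFrame([[0, 2, 5], [2, 0, 4], [5, 4, 0]], dtype=float)
        assert st.nmds(d, restarts=3, seed=0).stress < 1e-3

    def test_deterministic_given_seed(self, rng):
        pts = rng.random((8, 4))
        a = st.nmds(dist_df(pts), seed=3)
        b = st.nmds(dist_df(pts), seed=3)
        assert np.array_equal(a.coordinates.values, b.coordinates.values)
        assert a.stress == b.stress

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            st.nmds(pd.DataFrame([[0, 1], [2, 0]], dtype=float))


class TestAnosim:
    def test_perfect_separation_exhaustive(self):
        pts = [[0, 0], [0.1, 0], [0, 0.1], [10, 10], [10.1, 10], [10, 10.1]]
        res = st.anosim(dist_df(pts), ["a", "a", "a", "b", "b", "b"])
        assert res.R == pytest.approx(1.0)
        assert res.exhaustive
        assert res.p == pytest.approx(1 / 10)

    def test_all_equal_distances_give_zero_R(self):
        d = pd.DataFrame(1.0 - np.eye(6))
        res = st.anosim(d, ["a"] * 3 + ["b"] * 3)
        assert res.R == pytest.approx(0.0)

    def test_null_R_centred_near_zero(self, rng):
        pts = rng.random((12, 3))
        d = dist_df(pts)
        rs = [st.anosim(d, rng.permutation(["a"] * 6 + ["b"] * 6),
                        n_permutations=99, seed=i, exhaustive_limit=0).R
              for i in range(20)]
        assert abs(np.mean(rs)) < 0.15

    def test_rank_invariance_under_monotone_transform(self, rng):
        pts = rng.random((10, 3))
        d = dist_df(pts)
        g = ["a"] * 5 + ["b"] * 5
        r1 = st.anosim(d, g, n_permutations=49, seed=0).R
        r2 = st.anosim(d ** 3, g, n_permutations=49, seed=0).R
        assert r1 == pytest.approx(r2)

    def test_matches_reference_R(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import anosim as sk_anosim
        pts = rng.random((12, 4))
        d = dist_df(pts)
        g = ["a", "b"] * 6
        ours = st.anosim(d, g, n_permutations=99, seed=0, exhaustive_limit=0)
        ref = sk_anosim(DistanceMatrix(d.values), g, permutations=99)
        assert ours.R == pytest.approx(ref["test statistic"])

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            st.anosim(dist_df([[0], [1], [2]]), ["a", "a", "b"])


class TestPermanova:
    def test_duplicate_points_within_groups(self):
        pts = [[0, 0], [0, 0], [5, 5], [5, 5]]
        res = st.permanova(dist_df(pts), ["a", "a", "b", "b"],
                           n_permutations=99, seed=0)
        assert res.R2 == pytest.approx(1.0)

    def test_two_tight_clouds_direct_ss_oracle(self, rng):
        a = rng.normal(0, 0.05, (6, 2))
        b = rng.normal(5, 0.05, (6, 2)) + [5, 0]
        pts = np.vstack([a, b])
        g = np.array(["a"] * 6 + ["b"] * 6)
        res = st.permanova(dist_df(pts), g, n_permutations=99, seed=0)
        assert res.R2 > 0.9
        # independent oracle: Gower decomposition recomputed from scratch
        d2 = squareform(pdist(pts)) ** 2
        n = len(g)
        ss_tot = d2[np.triu_indices(n, 1)].sum() / n
        ss_w = sum(d2[np.ix_(g == lab, g == lab)][np.triu_indices(6, 1)].sum() / 6
                   for lab in ("a", "b"))
        assert res.R2 == pytest.approx((ss_tot - ss_w) / ss_tot)

    def test_null_R2_matches_expectation(self, rng):
        n, reps = 12, 200
        r2s = []
        for i in range(reps):
            pts = rng.random((n, 3))
            g = rng.permutation(["a"] * 6 + ["b"] * 6)
            d2 = squareform(pdist(pts)) ** 2
            ss_tot = d2[np.triu_indices(n, 1)].sum() / n
            ss_w = sum(d2[np.ix_(g == lab, g == lab)][np.triu_indices(6, 1)].sum() / 6
                       for lab in ("a", "b"))
            r2s.append((ss_tot - ss_w) / ss_tot)
        assert np.mean(r2s) == pytest.approx(1 / (n - 1), abs=0.02)

    def test_matches_reference_pseudo_F(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as sk_permanova
        pts = rng.random((12, 4))
        d = dist_df(pts)
        g = ["a", "b"] * 6
        ours = st.permanova(d, g, n_permutations=99, seed=0)
        ref = sk_permanova(DistanceMatrix(d.values), g, permutations=99)
        assert ours.pseudo_F == pytest.approx(ref["test statistic"])

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            st.permanova(dist_df([[0], [1], [2]]), ["a", "a", "a"])


class TestEnvfit:
    def _ord(self, pts):
        return st.Ordination(pd.DataFrame(pts, columns=["NMDS1", "NMDS2"]),
                             0.0, 1, 0)

    def test_axis_variable_perfect_fit(self, rng):
        pts = rng.random((20, 2))
        res = st.envfit(self._ord(pts), pts[:, 0], "x", n_permutations=99, seed=0)
        assert res.r2 == pytest.approx(1.0)
        assert res.p <= 0.05

    def test_noise_variable_weak_fit(self, rng):
        pts = rng.random((200, 2))
        res = st.envfit(self._ord(pts), rng.random(200), "noise",
                        n_permutations=99, seed=0)
        assert res.r2 < 0.05

    def test_constant_variable_zero(self, rng):
        res = st.envfit(self._ord(rng.random((10, 2))), np.ones(10), "const")
        assert res.r2 == 0.0


class TestBioenv:
    def test_generating_variable_recovered(self, rng):
        x = rng.random(12)
        env = pd.DataFrame({"X": x, "noise1": rng.random(12),
                            "noise2": rng.random(12)})
        zx = (x - x.mean()) / x.std(ddof=1)
        comm = pd.DataFrame(squareform(pdist(zx[:, None])))
        res = st.bioenv(comm, env)
        assert res.best_subset == ("X",)
        assert res.rho > 0.98

    def test_subset_count_is_2_to_n_minus_1(self, rng):
        env = pd.DataFrame(rng.random((8, 4)), columns=list("abcd"))
        comm = pd.DataFrame(squareform(pdist(rng.random((8, 2)))))
        res = st.bioenv(comm, env)
        assert len(res.table) == 15

    def test_matches_naive_recomputation(self, rng):
        env = pd.DataFrame(rng.random((10, 3)), columns=list("pqr"))
        commd = squareform(pdist(rng.random((10, 2))))
        res = st.bioenv(pd.DataFrame(commd), env)
        # independent oracle: direct loop over all subsets
        iu = np.triu_indices(10, 1)
        z = (env - env.mean()) / env.std(ddof=1)
        best = (-np.inf, None)
        for size in (1, 2, 3):
            for sub in itertools.combinations(env.columns, size):
                rho = spearmanr(commd[iu], pdist(z[list(sub)].values)).statistic
                if rho > best[0]:
                    best = (rho, sub)
        assert res.best_subset == best[1]
        assert res.rho == pytest.approx(best[0])

    def test_null_rho_small(self, rng):
        comm = pd.DataFrame(squareform(pdist(rng.random((30, 5)))))
        env = pd.DataFrame(rng.random((30, 3)), columns=list("abc"))
        assert st.bioenv(comm, env).rho < 0.3


class TestWilcoxon:
    def test_field_salinity_pairs_exact_p(self):
        md = load_field_metadata()
        loc = md[md.site == "LOC"].set_index("date")["salinity_ppt"]
        rb = md[md.site == "RB"].set_index("date")["salinity_ppt"]
        w_plus, p = st.wilcoxon_signed_rank(loc.values, rb.loc[loc.index].values)
        assert p == pytest.approx(0.015625)
        # independent oracle: complete enumeration of all 2^8 sign vectors
        d = loc.values - rb.loc[loc.index].values
        ranks = rankdata(np.abs(d))
        obs = ranks[d > 0].sum()
        ws = [sum(r for r, s in zip(ranks, signs) if s)
              for signs in itertools.product([0, 1], repeat=8)]
        p_le = sum(w <= obs for w in ws) / 256
        p_ge = sum(w >= obs for w in ws) / 256
        assert p == pytest.approx(min(1.0, 2 * min(p_le, p_ge)))

    def test_all_positive_differences_minimum_p(self):
        a = np.arange(1.0, 9.0) * 10
        b = a - np.arange(1.0, 9.0)
        _, p = st.wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(2 / 256)

    def test_identical_samples_rejected(self):
        with pytest.raises(ValueError):
            st.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_matches_scipy_exact(self, rng):
        from scipy.stats import wilcoxon
        for _ in range(5):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0.3, 1, 12)
            _, p = st.wilcoxon_signed_rank(a, b)
            ref = wilcoxon(a, b, mode="exact", alternative="two-sided")
            assert p == pytest.approx(ref.pvalue)


class TestSiteSummary:
    def test_field_table_headline_contrasts(self):
        ss = st.site_summary(load_field_metadata())
        assert round(ss.loc["temp_C", "difference"], 1) == 1.4
        assert round(ss.loc["salinity_ppt", "difference"], 1) == 17.9
        assert round(ss.loc["autofluor_cells_per_mL", "ratio_LOC_over_RB"], 1) == 12.3
        assert round(ss.loc["nh4_uM", "ratio_RB_over_LOC"], 1) == 3.5
        assert ss.loc["salinity_ppt", "wilcoxon_p"] == pytest.approx(0.015625)

    def test_identical_sites_give_null_contrasts(self):
        md = load_field_metadata()
        clone = md[md.site == "LOC"].copy()
        clone["site"] = "RB"
        both = pd.concat([md[md.site == "LOC"], clone])
        ss = st.site_summary(both)
        assert np.allclose(ss["difference"], 0)
        assert np.allclose(ss["ratio_LOC_over_RB"].astype(float), 1)
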
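import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from conftest import truth_label_maps
from halovir import temporal as tp


def make_profiles(rng, centers, n_per, length=16, noise=0.3):
    """Well-separated synthetic Z-profiles around given archetypes."""
    profiles, labels = [], []
    for ci, c in enumerate(centers):
        arch = np.zeros(length)
        arch[c] = 3.0
        for j in range(n_per):
            v = arch + rng.normal(0, noise, length)
            v = (v - v.mean()) / v.std()
            profiles.append(tp.ZProfile(f"c{ci}_v{j}", v))
            labels.append(ci)
    return profiles, labels


class TestSizeFactors:
    def test_scaled_columns_recover_ratio(self):
        a = pd.DataFrame({"s1": [10, 20, 30], "s2": [20, 40, 60]})
        f = tp.size_factors(a)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)

    def test_identical_columns_unit_factors(self):
        a = pd.DataFrame({"s1": [5, 7, 9], "s2": [5, 7, 9]})
        assert np.allclose(tp.size_factors(a), 1.0)

    def test_single_feature_proportional_to_counts(self):
        a = pd.DataFrame({"s1": [10], "s2": [40]})
        f = tp.size_factors(a)
        assert f["s2"] / f["s1"] == pytest.approx(4.0)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError, match="s2"):
            tp.size_factors(pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}))


class TestNormalizeDetrendScale:
    def test_linear_profile_dropped_as_constant(self):
        t = np.arange(8)
        counts = pd.DataFrame({f"s{i}": [int(round(np.expm1(0.5 * t[i]))), 50]
                               for i in range(8)})
        profiles = tp.normalize_detrend_scale(counts)
        # the exactly-linear (in log space) first row detrends to a constant
        assert len(profiles) <= 1

    def test_spike_dominates_z(self):
        counts = pd.DataFrame([[10, 10, 10, 500, 10, 10, 10, 10],
                               [20, 21, 19, 20, 22, 18, 20, 21]],
                              columns=[f"s{i}" for i in range(8)])
        profiles = tp.normalize_detrend_scale(counts)
        spike = profiles[0].values
        assert int(np.argmax(spike)) == 3

    def test_output_standardised(self, pipeline_result):
        for p in pipeline_result.zprofiles:
            assert abs(p.values.mean()) < 1e-8
            assert p.values.std() == pytest.approx(1.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            tp.normalize_detrend_scale(pd.DataFrame({"a": [1], "b": [2]}))


class TestKmedoids:
    def test_k1_medoid_minimises_total_distance(self, rng):
        profiles, _ = make_profiles(rng, [2, 9], 4)
        medoids, assign = tp.kmedoids(profiles, 1)
        X = np.vstack([p.values for p in profiles])
        D = squareform(pdist(X))
        # brute-force oracle over every candidate medoid
        best = int(np.argmin(D.sum(axis=1)))
        assert medoids == [profiles[best].votu_id]
        assert set(assign.values()) == {0}

    def test_two_planted_groups_recovered(self, rng):
        profiles, labels = make_profiles(rng, [2, 12], 8)
        _, assign = tp.kmedoids(profiles, 2)
        pred = [assign[p.votu_id] for p in profiles]
        assert adjusted_rand_score(labels, pred) == 1.0

    def test_k_equals_n_zero_objective(self, rng):
        profiles, _ = make_profiles(rng, [1, 8], 2)
        medoids, assign = tp.kmedoids(profiles, len(profiles))
        assert sorted(medoids) == sorted(p.votu_id for p in profiles)
        assert sorted(assign.values()) == list(range(len(profiles)))

    def test_k_above_n_rejected(self, rng):
        profiles, _ = make_profiles(rng, [3], 3)
        with pytest.raises(ValueError):
            tp.kmedoids(profiles, 10)


class TestSelectK:
    @pytest.mark.parametrize("k_true", [3, 4, 5, 6])
    def test_planted_k_recovered(self, rng, k_true):
        centers = np.linspace(1, 14, k_true).astype(int)
        profiles, labels = make_profiles(rng, centers, 10)
        model = tp.select_k(profiles, range(1, 13), seed=0)
        assert model.chosen_k == k_true
        pred = [model.assignment[p.votu_id] for p in profiles]
        assert adjusted_rand_score(labels, pred) == 1.0

    def test_unstructured_blob_returns_curves_without_failure(self, rng):
        profiles = [tp.ZProfile(f"v{i}",
                                (lambda x: (x - x.mean()) / x.std())(rng.normal(0, 1, 16)))
                    for i in range(30)]
        model = tp.select_k(profiles, range(1, 10), seed=0)
        assert set(model.sse_by_k) == {"pam", "ward"}
        assert max(v for k, v in model.silhouette_by_k.items()
                   if not np.isnan(v)) < 0.3

    def test_deterministic(self, rng):
        profiles, _ = make_profiles(rng, [2, 8, 13], 6)
        a = tp.select_k(profiles, range(1, 10), seed=5)
        b = tp.select_k(profiles, range(1, 10), seed=5)
        assert a.chosen_k == b.chosen_k
        assert a.assignment == b.assignment

    def test_sse_curves_nonincreasing_in_k(self, pipeline_result):
        for method in ("pam", "ward"):
            curve = pipeline_result.cluster_model.sse_by_k[method]
            ks = sorted(curve)
            assert all(curve[a] >= curve[b] - 1e-9
                       for a, b in zip(ks, ks[1:]))


class TestPipelineRecovery:
    def test_planted_temporal_clusters_recovered(self, dataset, pipeline_result):
        model = pipeline_result.cluster_model
        _, votu_true = truth_label_maps(dataset, pipeline_result.votus)
        truth_cluster = dataset.truth.temporal_cluster
        ids = [v for v in model.assignment if votu_true[v] in truth_cluster]
        true = [truth_cluster[votu_true[v]] for v in ids]
        pred = [model.assignment[v] for v in ids]
        assert model.chosen_k == dataset.config.n_planted_temporal_clusters
        assert adjusted_rand_score(true, pred) >= 0.9

    def test_planted_amg_enrichment_has_top_z(self, dataset, pipeline_result):
        model = pipeline_result.cluster_model
        _, votu_true = truth_label_maps(dataset, pipeline_result.votus)
        truth = dataset.truth
        hits = total = 0
        for cp in pipeline_result.cluster_profiles:
            members = [v for v, c in model.assignment.items() if c == cp.cluster]
            tcs = [truth.temporal_cluster[votu_true[v]] for v in members
                   if votu_true[v] in truth.temporal_cluster]
            if not tcs or cp.pathway_z.empty:
                continue
            planted = truth.enriched_pathway[max(set(tcs), key=tcs.count)]
            total += 1
            if cp.pathway_z.idxmax() == planted:
                hits += 1
        assert total >= 3 and hits == total

    def test_single_family_cluster_has_max_family_z(self, rng):
        profiles, labels = make_profiles(rng, [2, 12], 5)
        model = tp.select_k(profiles, range(1, 6), seed=0)
        ids = [p.votu_id for p in profiles]
        abundance = pd.DataFrame(rng.random((len(ids), 16)) + 0.5, index=ids)
        fam = ["Zobellviridae" if l == 0 else "Kyanoviridae" for l in labels]
        tax = pd.DataFrame({"votu_id": ids, "family": fam})
        amg = pd.DataFrame({"votu_id": [ids[0]], "gene_id": ["g"],
                            "kegg_pathway": ["Photosynthesis"],
                            "contig_id": ["c"]})
        profs = tp.profile_clusters(model, profiles, abundance, tax, amg)
        for cp in profs:
            members = [v for v, c in model.assignment.items() if c == cp.cluster]
            major = pd.Series([fam[ids.index(m)] for m in members]).mode()[0]
            assert cp.family_z.idxmax() == major

    def test_absent_pathway_flagged(self, rng):
        profiles, _ = make_profiles(rng, [2, 12], 4)
        model = tp.select_k(profiles, range(1, 5), seed=0)
        ids = [p.votu_id for p in profiles]
        abundance = pd.DataFrame(np.ones((len(ids), 16)), index=ids)
        tax = pd.DataFrame({"votu_id": ids, "family": ["F"] * len(ids)})
        amg = pd.DataFrame({"votu_id": [ids[0]], "gene_id": ["g"],
                            "kegg_pathway": ["Sulfur metabolism"],
                            "contig_id": ["c"]})
        profs = tp.profile_clusters(model, profiles, abundance, tax, amg)
        cluster_of_first = model.assignment[ids[0]]
        for cp in profs:
            if cp.cluster != cluster_of_first:
                assert "Sulfur metabolism" in cp.absent_pathways
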
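import numpy as np
import pytest

from halovir.clustering import ani_oracle_dp
from halovir.io import write_fasta
from halovir.simulate import (SimConfig, SimConfigError, generate_contigs,
                              generate_metadata, generate_predictor_calls,
                              generate_alignments, simulate_dataset,
                              write_fixture)


class TestMetadata:
    def test_one_row_per_site_date_with_one_pulse_per_site(self):
        md = generate_metadata(SimConfig(seed=3))
        assert len(md) == 16
        for site, sub in md.groupby("site"):
            assert (sub["salinity_ppt"] < 32).sum() == 1
            assert sub.loc[sub["is_pulse"] == 1, "salinity_ppt"].iloc[0] < 32
            assert sub["is_freeze"].sum() == 2

    def test_site_salinity_contrast_matches_configured_means(self):
        diffs = []
        for seed in range(30):
            md = generate_metadata(SimConfig(seed=seed))
            means = md.groupby("site")["salinity_ppt"].mean()
            diffs.append(means["LOC"] - means["RB"])
        assert abs(np.mean(diffs) - 17.9) < 1.0

    def test_deterministic_given_seed(self):
        a = generate_metadata(SimConfig(seed=1))
        b = generate_metadata(SimConfig(seed=1))
        assert a.equals(b)

    def test_zero_samples_is_invalid(self):
        with pytest.raises(SimConfigError):
            SimConfig(seed=0, n_dates=0)


class TestContigs:
    def test_sibling_pairs_cohere_at_votu_threshold(self, rng):
        cfg = SimConfig(seed=5, n_votus=4, contigs_per_votu=(2, 3),
                        contig_length_range=(2_000, 3_000),
                        within_votu_divergence=0.02, n_decoys=0,
                        short_viral_fraction=0.0)
        contigs, truth = generate_contigs(cfg)
        by_votu = {}
        for cid, v in truth.votu_assignment.items():
            by_votu.setdefault(v, []).append(cid)
        checked = 0
        for members in by_votu.values():
            for a, b in zip(members, members[1:]):
                r = ani_oracle_dp(contigs[a], contigs[b])
                assert r.ani >= 0.95
                assert r.aligned_fraction >= 0.85
                checked += 1
        assert checked > 0

    def test_single_member_votus_give_bijection(self):
        cfg = SimConfig(seed=2, n_votus=10, contigs_per_votu=(1, 1),
                        n_decoys=0, short_viral_fraction=0.0)
        contigs, truth = generate_contigs(cfg)
        assert len(set(truth.votu_assignment.values())) == len(truth.votu_assignment)
        assert len(contigs) == 10

    def test_every_contig_assigned_exactly_once(self, dataset):
        assert set(dataset.contigs) == set(dataset.truth.votu_assignment)

    def test_fasta_bytes_identical_across_runs(self, tmp_path, sim_config):
        paths = []
        for name in ("a", "b"):
            contigs, _ = generate_contigs(sim_config)
            p = tmp_path / f"{name}.fasta"
            write_fasta(contigs, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_invalid_length_range_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(seed=0, contig_length_range=(0, 10))


class TestPredictorCalls:
    def _contigs(self, **kw):
        cfg = SimConfig(seed=4, n_votus=8, contigs_per_votu=(1, 2),
                        n_decoys=5, short_viral_fraction=0.0,
                        trimmed_call_fraction=0.0, **kw)
        return cfg, *generate_contigs(cfg)

    def test_perfect_predictors_call_each_viral_contig_four_times(self):
        cfg, contigs, truth = self._contigs(
            predictor_sensitivity=(1, 1, 1, 1), predictor_fpr=(0, 0, 0, 0))
        calls = generate_predictor_calls(contigs, truth, cfg)
        viral = [c for c, f in truth.viral_flag.items() if f]
        assert len(calls) == 4 * len(viral)
        assert set(calls["contig_id"].str.split("\\|\\|").str[0]) == set(viral)

    @pytest.mark.parametrize("sens,expected_calls_per_contig", [
        ((1, 1, 0, 0), 2), ((1, 0, 0, 0), 1)])
    def test_partial_sensitivity_vote_counts(self, sens, expected_calls_per_contig):
        cfg, contigs, truth = self._contigs(
            predictor_sensitivity=sens, predictor_fpr=(0, 0, 0, 0))
        calls = generate_predictor_calls(contigs, truth, cfg)
        per_contig = calls.groupby("contig_id").size()
        assert (per_contig == expected_calls_per_contig).all()

    def test_probabilities_outside_unit_interval_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(seed=0, predictor_sensitivity=(1.2, 1, 1, 1))


class TestAlignments:
    def test_absent_cells_are_silent_without_stray_signal(self):
        cfg = SimConfig(seed=6, n_votus=10, stray_signal_fraction=0.0,
                        n_decoys=0, short_viral_fraction=0.0)
        contigs, truth = generate_contigs(cfg)
        counts, coverage, _ = generate_alignments(contigs, truth, cfg)
        covered = set(zip(coverage["contig_id"], coverage["sample_id"]))
        for _, row in counts.iterrows():
            v = truth.votu_assignment[row["contig_id"]]
            assert truth.presence.loc[v, row["sample_id"]]
        for cid, s in covered:
            v = truth.votu_assignment[cid]
            assert truth.presence.loc[v, s]

    def test_detected_cells_have_breadth_above_threshold(self, dataset):
        cov = dataset.coverage
        truth = dataset.truth
        lengths = {c: len(s) for c, s in dataset.contigs.items()}
        for (cid, s), sub in cov.groupby(["contig_id", "sample_id"]):
            v = truth.votu_assignment[cid]
            if not v.startswith("tv"):
                continue
            total = sum(e - b for b, e in zip(sub["start"], sub["end"]))
            breadth = total / lengths[cid]
            if truth.presence.loc[v, s]:
                assert breadth > 0.75
            else:
                assert breadth <= 0.75

    def test_tables_identical_across_runs(self, sim_config, dataset):
        again = simulate_dataset(sim_config)
        assert again.read_counts.equals(dataset.read_counts)
        assert again.coverage.equals(dataset.coverage)
        assert again.sample_depths.equals(dataset.sample_depths)


class TestAnnotations:
    def test_amg_pathways_drawn_from_pool(self, dataset):
        assert set(dataset.amg["kegg_pathway"]) <= set(dataset.config.kegg_pool)

    def test_empty_lineage_pool_rejected(self):
        with pytest.raises(SimConfigError):
            SimConfig(seed=0, lineage_pool=())

    def test_fixture_directory_is_deterministic(self, tmp_path, sim_config):
        for name in ("a", "b"):
            write_fixture(simulate_dataset(sim_config), tmp_path / name)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name
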
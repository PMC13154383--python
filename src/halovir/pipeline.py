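"""End-to-end orchestration of the analysis stages.

``run_pipeline`` takes the raw inputs (as produced by the synthetic
generator or read from a fixture directory) and chains consensus ->
clustering -> abundance -> taxonomy -> community statistics -> temporal
clustering -> virus-host network, returning everything in a single result
object.  ``save_results`` writes the standard TSV/JSON outputs; the CLI is
a thin wrapper over these two calls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from halovir import abundance as ab
from halovir import clustering as cl
from halovir import consensus as cs
from halovir import hosts as ho
from halovir import stats as st
from halovir import taxonomy as tx
from halovir import temporal as tp
from halovir.config import RunConfig
from halovir.io import parse_contig_id, strip_trim_suffix, write_table

logger = logging.getLogger("halovir")


@dataclass
class PipelineInputs:
    contigs: dict[str, str]
    predictor_calls: pd.DataFrame
    read_counts: pd.DataFrame
    coverage: pd.DataFrame
    sample_depths: pd.DataFrame
    metadata: pd.DataFrame
    gene_taxonomy: pd.DataFrame | None = None
    amg: pd.DataFrame | None = None
    host_predictions: pd.DataFrame | None = None
    mags: pd.DataFrame | None = None

    @classmethod
    def from_dataset(cls, ds) -> "PipelineInputs":
        return cls(contigs=ds.contigs, predictor_calls=ds.predictor_calls,
                   read_counts=ds.read_counts, coverage=ds.coverage,
                   sample_depths=ds.sample_depths, metadata=ds.metadata,
                   gene_taxonomy=ds.gene_taxonomy, amg=ds.amg,
                   host_predictions=ds.host_predictions, mags=ds.mags)

    @classmethod
    def from_fixture_dir(cls, path: str | Path) -> "PipelineInputs":
        from halovir import io as hio
        path = Path(path)
        return cls(
            contigs=hio.read_fasta(path / "contigs.fasta"),
            predictor_calls=hio.read_table(path / "predictor_calls.tsv", "predictor_calls"),
            read_counts=hio.read_table(path / "read_counts.tsv", "read_counts"),
            coverage=hio.read_table(path / "coverage.tsv", "coverage"),
            sample_depths=hio.read_table(path / "sample_depths.tsv", "sample_depths"),
            metadata=hio.read_table(path / "metadata.tsv", "metadata"),
            gene_taxonomy=hio.read_table(path / "gene_taxonomy.tsv", "gene_taxonomy"),
            amg=hio.read_table(path / "amg.tsv", "amg"),
            host_predictions=hio.read_table(path / "host_predictions.tsv", "host_predictions"),
            mags=hio.read_table(path / "mags.tsv", "mags"),
        )


@dataclass
class PipelineResult:
    config: RunConfig
    consensus_records: list
    votus: list
    membership: pd.DataFrame
    membership_aggregate: pd.DataFrame
    abundance: ab.AbundanceMatrix
    votu_taxonomy: pd.DataFrame | None
    diversity: pd.DataFrame | None = None
    distances: pd.DataFrame | None = None
    ordination: st.Ordination | None = None
    anosim_site: st.AnosimResult | None = None
    anosim_season: st.AnosimResult | None = None
    permanova_site: st.PermanovaResult | None = None
    envfit_results: list = field(default_factory=list)
    bioenv_result: st.BioenvResult | None = None
    site_summary: pd.DataFrame | None = None
    zprofiles: list = field(default_factory=list)
    cluster_model: tp.ClusterModel | None = None
    cluster_profiles: list = field(default_factory=list)
    host_edges: list = field(default_factory=list)
    network_per_order: pd.DataFrame | None = None
    network_multi_order: pd.DataFrame | None = None
    network_totals: dict = field(default_factory=dict)


def _sample_grouping(samples: list[str], metadata: pd.DataFrame) -> pd.DataFrame:
    meta = metadata.assign(sample_id=metadata["site"] + "_" + metadata["date"])
    meta = meta.set_index("sample_id")
    missing = [s for s in samples if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    return meta.loc[samples]


def run_pipeline(inputs: PipelineInputs, config: RunConfig | None = None,
                 run_stats: bool = True, run_temporal: bool = True,
                 run_hosts: bool = True) -> PipelineResult:
    """Run every stage; later stage groups can be switched off."""
    cfg = config or RunConfig()
    delim = cfg.trim_delimiter

    records = cs.dedupe_calls(inputs.predictor_calls, inputs.contigs, delim)
    passing = cs.consensus_filter(records, cfg.min_length_bp, cfg.min_tools)
    sequences = {r.kept_contig_id: r.kept_sequence for r in passing}
    votus = cl.cluster_votus(sequences, cfg.ani_min, cfg.af_min, delim)
    membership, agg = cl.summarize_membership(votus, delimiter=delim)

    contig_lengths = {c: len(s) for c, s in inputs.contigs.items()}
    mat = ab.build_matrix(inputs.read_counts, inputs.coverage,
                          inputs.sample_depths, votus, contig_lengths,
                          cfg.breadth_threshold, delim)

    votu_tax = None
    if inputs.gene_taxonomy is not None:
        votu_tax = tx.assign_votu_taxonomy(inputs.gene_taxonomy, votus,
                                           cfg.majority_fraction,
                                           cfg.pool_member_genes, delim)

    result = PipelineResult(cfg, records, votus, membership, agg, mat, votu_tax)

    samples = list(mat.values.columns)
    if run_stats:
        grouping = _sample_grouping(samples, inputs.metadata)
        div_rows = []
        for s in samples:
            col = mat.values[s]
            if col.sum() > 0:
                d = st.diversity(col)
                div_rows.append({"sample_id": s, "shannon": d.shannon,
                                 "pielou": d.pielou, "richness": d.richness})
        result.diversity = pd.DataFrame(div_rows)
        result.distances = st.community_distances(mat.values, cfg.distance)
        result.ordination = st.nmds(result.distances, seed=cfg.seed)
        result.anosim_site = st.anosim(result.distances, grouping["site"],
                                       cfg.n_permutations, cfg.seed)
        result.anosim_season = st.anosim(result.distances, grouping["season"],
                                         cfg.n_permutations, cfg.seed)
        result.permanova_site = st.permanova(result.distances, grouping["site"],
                                             cfg.n_permutations, cfg.seed)
        env_cols = [c for c in st.ABIOTIC_COLUMNS if c in grouping.columns]
        result.envfit_results = [
            st.envfit(result.ordination, grouping[c].astype(float), c,
                      min(cfg.n_permutations, 999), cfg.seed)
            for c in env_cols]
        result.bioenv_result = st.bioenv(result.distances,
                                         grouping[env_cols].astype(float),
                                         max_subset_size=5)
        result.site_summary = st.site_summary(inputs.metadata)

    if run_temporal and mat.counts.shape[0] >= 4:
        result.zprofiles = tp.normalize_detrend_scale(mat.counts, samples)
        n = len(result.zprofiles)
        if n >= 4:
            kr = range(cfg.k_min, min(cfg.k_max, n - 1) + 1)
            result.cluster_model = tp.select_k(result.zprofiles, kr, cfg.seed)
            amg_votu = None
            if inputs.amg is not None and not inputs.amg.empty:
                amg_votu = map_amg_to_votus(inputs.amg, votus, delim)
            if votu_tax is not None:
                result.cluster_profiles = tp.profile_clusters(
                    result.cluster_model, result.zprofiles, mat.values,
                    votu_tax, amg_votu)

    if run_hosts and inputs.host_predictions is not None and inputs.mags is not None:
        mags = ho.classify_mags(inputs.mags)
        clusters = {}
        if result.cluster_model is not None:
            clusters = {v: f"cl{c}" for v, c in result.cluster_model.assignment.items()}
        site_class = dict(zip(membership["votu_id"], membership["site_class"])) \
            if not membership.empty else {}
        result.host_edges = ho.filter_predictions(
            inputs.host_predictions, votus, mags, clusters, site_class, delim)
        mag_ab = dict(zip(inputs.mags["mag_id"],
                          inputs.mags["relative_abundance"].astype(float))) \
            if "relative_abundance" in inputs.mags else {}
        per_order, multi, totals = ho.network_summary(result.host_edges, mag_ab)
        result.network_per_order = per_order
        result.network_multi_order = multi
        result.network_totals = totals
    return result


def map_amg_to_votus(amg: pd.DataFrame, votus, delimiter: str = "||") -> pd.DataFrame:
    """Attach vOTU ids to contig-level AMG annotations (unmapped rows drop)."""
    votu_of = {}
    for v in votus:
        for m in v.members:
            votu_of[strip_trim_suffix(m, delimiter)] = v.votu_id
    out = amg.copy()
    out["votu_id"] = out["contig_id"].map(
        lambda c: votu_of.get(strip_trim_suffix(c, delimiter)))
    return out.dropna(subset=["votu_id"]).reset_index(drop=True)


def save_results(result: PipelineResult, outdir: str | Path) -> None:
    """Write the standard result tables (TSV) and test statistics (JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cons = pd.DataFrame([{
        "base_name": r.base_name, "kept_contig_id": r.kept_contig_id,
        "kept_length_bp": r.kept_length_bp,
        "supporting_predictors": ",".join(sorted(r.supporting_predictors)),
        "passed": int(r.passed), "fail_reason": r.fail_reason,
    } for r in result.consensus_records])
    write_table(cons, out / "consensus.tsv")
    vot = pd.DataFrame([{
        "votu_id": v.votu_id, "representative": v.representative,
        "members": ",".join(sorted(v.members)),
    } for v in result.votus])
    write_table(vot, out / "votus.tsv")
    write_table(result.membership, out / "votu_membership.tsv")
    write_table(result.membership_aggregate, out / "votu_membership_aggregate.tsv")
    write_table(cl.site_class_counts(result.membership)
                .rename_axis("site_class").reset_index(name="n_votus"),
                out / "votu_site_class_counts.tsv")
    write_table(result.abundance.values.rename_axis("votu_id").reset_index(),
                out / "abundance.tsv")
    write_table(result.abundance.counts.rename_axis("votu_id").reset_index(),
                out / "votu_counts_unfiltered.tsv")
    if result.votu_taxonomy is not None:
        write_table(result.votu_taxonomy, out / "votu_taxonomy.tsv")
    if result.diversity is not None:
        write_table(result.diversity, out / "diversity.tsv")
    if result.ordination is not None:
        write_table(result.ordination.coordinates.rename_axis("sample_id").reset_index(),
                    out / "nmds_coordinates.tsv")
    stats_json: dict = {}
    if result.anosim_site is not None:
        stats_json["anosim_site"] = {"R": result.anosim_site.R, "p": result.anosim_site.p}
        stats_json["anosim_season"] = {"R": result.anosim_season.R,
                                       "p": result.anosim_season.p}
        stats_json["permanova_site"] = {"pseudo_F": result.permanova_site.pseudo_F,
                                        "R2": result.permanova_site.R2,
                                        "p": result.permanova_site.p}
        stats_json["nmds_stress"] = result.ordination.stress
        stats_json["envfit"] = {e.variable: {"r2": e.r2, "p": e.p}
                                for e in result.envfit_results}
        if result.bioenv_result is not None:
            stats_json["bioenv"] = {"best_subset": list(result.bioenv_result.best_subset),
                                    "rho": result.bioenv_result.rho}
    if result.cluster_model is not None:
        m = result.cluster_model
        stats_json["temporal"] = {"chosen_k": m.chosen_k,
                                  "candidate_ks": list(m.candidate_ks),
                                  "silhouette_by_k": {str(k): None if np.isnan(v) else v
                                                      for k, v in m.silhouette_by_k.items()}}
        assign = pd.DataFrame({"votu_id": list(m.assignment),
                               "cluster": [f"cl{c}" for c in m.assignment.values()]})
        write_table(assign, out / "temporal_clusters.tsv")
    if result.site_summary is not None:
        write_table(result.site_summary.reset_index(), out / "site_summary.tsv")
    if result.network_per_order is not None:
        write_table(result.network_per_order, out / "network_per_order.tsv")
        write_table(result.network_multi_order, out / "network_multi_order.tsv")
        stats_json["network_totals"] = result.network_totals
    edges = pd.DataFrame([{
        "votu_id": e.votu_id, "mag_id": e.mag_id, "host_order": e.host_order,
        "host_class": e.host_class, "host_phylum": e.host_phylum,
        "score": e.score, "votu_cluster": e.votu_cluster,
        "votu_site_class": e.votu_site_class,
    } for e in result.host_edges])
    if not edges.empty:
        write_table(edges, out / "host_edges.tsv")
    (out / "statistics.json").write_text(json.dumps(stats_json, indent=2,
                                                    default=float))
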
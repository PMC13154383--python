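# Table schemas

All tables are tab-separated UTF-8 with one header row; missing values are
empty strings; dates are ISO-8601; coordinates are 0-based half-open.
`halovir.io.read_table(path, schema_name)` validates files against these
schemas (missing columns are an error; extra columns are preserved with a
warning). Lines starting with `#` are comments.

## Inputs (fixture directory)

### `metadata` — one row per site-date
| column | type | notes |
|---|---|---|
| site | str | e.g. LOC / RB |
| date | str | ISO-8601 |
| season | str | Spring/Summer/Fall/Winter |
| temp_C, do_mg_per_L, salinity_ppt, pH | float | salinity ≥ 0 |
| nh4_uM, no3_uM, no2_uM | float | printed means |
| autofluor_cells_per_mL | float | |
| is_pulse, is_freeze | int | 0/1 disturbance flags |

### `predictor_calls`
| column | type | notes |
|---|---|---|
| contig_id | str | may carry a trim suffix `<base>\|\|<start>_<end>` |
| predictor | str | tool name |
| called_length_bp | int | ≤ source contig length |

### `read_counts`
`sample_id (str), contig_id (str), reads (int ≥ 0)` — reads mapped per
contig per sample.

### `coverage`
`sample_id (str), contig_id (str), start (int), end (int)` — covered
intervals, 0-based half-open, within the contig.

### `sample_depths`
`sample_id (str), total_reads (int > 0)`.

### `gene_taxonomy`
`contig_id, gene_id, realm, kingdom, phylum, class, order, family,
environment` — all str; empty string = unannotated at that rank /
unlabelled environment.

### `amg`
`contig_id, gene_id, kegg_pathway` — one row per auxiliary metabolic gene.

### `host_predictions`
`virus_id (str), host_genome (str), score (float)` — virus ids may be any
member contig of a vOTU; host ids may reference MAGs or external genomes.

### `mags`
`mag_id, completion (0–100), contamination (0–100), domain, phylum, class,
order, length_bp (int), relative_abundance (float)`.

### Ground truth (written by `simulate`)
* `truth_votu_assignment`: `contig_id, votu_id, viral (0/1)`
* `truth_temporal_cluster`: `votu_id, cluster_id`
* `truth_abundance`: `votu_id` + one column per sample

## Outputs

* `consensus.tsv` — `base_name, kept_contig_id, kept_length_bp,
  supporting_predictors (comma-joined), passed (0/1), fail_reason`
* `consensus_passing.fasta` — kept sequences of passing contigs
* `votus.tsv` — `votu_id, representative, members (comma-joined)`
* `votu_membership.tsv` / `votu_membership_aggregate.tsv`
* `abundance.tsv` — `votu_id` + per-sample relative abundance
  (reads/kbp/million); `votu_counts_unfiltered.tsv` — raw vOTU counts
* `votu_taxonomy.tsv` — `votu_id, realm..family, environment`
* `diversity.tsv`, `nmds_coordinates.tsv`, `site_summary.tsv`
* `temporal_clusters.tsv` — `votu_id, cluster`; `cluster_profiles.tsv`
* `host_edges.tsv`, `network_per_order.tsv`, `network_multi_order.tsv`
* `statistics.json` — ANOSIM/PERMANOVA/envfit/bioenv/stress/model-selection
  summaries
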
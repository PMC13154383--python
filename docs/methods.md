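# Methods

This note documents the models, thresholds and numerical choices behind
each stage, what the synthetic generator does and does not emulate, and the
design decisions taken where the underlying protocol leaves the choice
open.

## Consensus viral identification

Calls from several prediction tools are treated as rows
`(contig_id, predictor, called_length)`. Tools that trim proviral regions
re-emit a contig under its base name plus a coordinate suffix
(`<base>||<start>_<end>`, 0-based half-open); variants sharing a base name
are collapsed to the **shortest** sequence, because the trimmed variant is
the more conservative viral region. Exact duplicate sequences are collapsed
on the as-given strand only (reverse-complement duplicates are *not*
collapsed, matching the behaviour of the standard dedupe tooling); the
supporting-predictor set is the union over all variants of a base name, and
the vote counts **distinct predictors**, not calls. Filters are strict:
`length > 10 000 bp` and `|predictors| ≥ 2`. A contig of exactly 10 000 bp
fails. The ≥ 2 vote is evaluated after name-variant collapsing — the union
of supporters — which is the reading most faithful to "concatenate, then
deduplicate". Ties among equally short variants break lexicographically so
the output is a pure function of the call set.

## ANI / AF and vOTU clustering

Two contigs belong to one vOTU when ANI ≥ 0.95 over an aligned fraction
≥ 0.85. Definitions:

* **ANI** — matches / (matches + mismatches) over the aligned columns of
  all alignment blocks; gap columns are excluded.
* **AF** — union length of block spans on the **shorter** sequence divided
  by its length (the standard dereplication convention; the denominator is
  otherwise ambiguous).

The production estimator seeds with exact 15-mers on both strands, bands
seed matches by diagonal (tolerance 30 bp, chain gap 500 bp), discards
chained blocks shorter than 100 bp, aligns each block globally with edlib
and accumulates the CIGAR match/mismatch counts. The oracle
(`ani_oracle_dp`) is an unrelated code path: full Smith–Waterman local
alignment (match +1, mismatch −2, gap open −4, extend −2) of the complete
sequences on both strands. The two agree within ±0.005 ANI on homologous
pairs up to 5 kb (asserted in the tests and measured by the acceptance
script); unrelated random sequences produce no chained blocks (AF 0) in the
seeded path and only short spurious local blocks (AF ≪ 0.85) in the oracle.

Clustering is greedy centroid: contigs sorted by length descending (ties by
id); each contig joins the qualifying representative of highest ANI
(earlier-founded representative on ties) or founds a new vOTU. The longest
member is therefore always the representative. On sets where clusters are
separated well beyond the thresholds this equals single-linkage
all-pairs clustering, which the tests verify against the oracle.

## Abundance

Coverage arrives as 0-based half-open interval tables; breadth is the
merged-union length over the representative contig divided by its length.
Detection is strict: `breadth > 0.75`. vOTU counts sum reads over all
member contigs (the aggregation rule is not dictated by the protocol; the
representative's length is used for normalisation). Relative abundance is
`reads / (length/1000) / (depth/10^6)` — reads per kbp per million sample
reads. Cells failing detection are zeroed in the community matrix but kept
in a parallel unfiltered count matrix, because the temporal analysis
deliberately uses all counts.

## Taxonomy

Per vOTU, ranks realm → family are walked shallow-to-deep; a label is
assigned when **strictly more than half** of the annotated genes carry it.
The denominator is genes with any annotation — unannotated genes do not
dilute the vote. The first rank without a strict majority and everything
below it become `Unknown <deepest assigned>`. By default the vote runs over
the representative contig's genes (`pool_member_genes` pools all members
instead; the protocol wording "on a contig" leaves this open). The source
environment uses the same strict majority over environment-labelled genes
with a fixed four-term vocabulary; unrecognised labels are warned and
ignored.

## Community statistics

All implemented from their defining formulas, with natural logarithms:

* Shannon `H = −Σ p_i ln p_i`, Pielou `J = H / ln S`, Chao1
  `S + F₁(F₁−1)/(2(F₂+1))` (integer counts only).
* CLR per sample: `x → ln(x+ε) − mean(ln(x+ε))`, ε = half the smallest
  nonzero matrix value when zeros are present (standard compositional
  practice). Community distance defaults to Euclidean on CLR rows;
  Bray–Curtis is available.
* NMDS: classical-scaling start (plus seeded jitter on restarts, default
  20), alternating isotonic regression of embedding distances on the
  dissimilarity order with Guttman-transform majorization; iteration stops
  the moment Kruskal stress-1 fails to decrease by 1e-7, so the stress
  trace is non-increasing within a restart; best restart reported.
* ANOSIM on mid-ranked distances; when the number of distinct label
  orderings is ≤ 10 000 the null is enumerated exhaustively (p = fraction
  of orderings with R ≥ observed, observed included — for two perfectly
  separated groups of three this gives p = 2/20 = 1/10); otherwise seeded
  permutations with the add-one rule so p is never zero.
* PERMANOVA from the Gower decomposition of squared distances;
  pseudo-F = (SS_b/df_b)/(SS_w/df_w); label-permutation p with add-one.
* envfit: R² of one variable regressed on the two ordination axes,
  permutation p; constant variables give r² = 0 with a warning.
* bioenv: variables z-scored; exhaustive subsets up to a size cap
  (mandatory above 20 variables); Spearman ρ between Euclidean subset
  distances and community distances over upper triangles.
* Wilcoxon signed-rank: zero differences dropped, mid-ranks for ties;
  exact two-sided p for n ≤ 25 by dynamic programming over doubled ranks
  (identical to enumerating all 2ⁿ sign vectors), tie-corrected normal
  approximation above.

Permutation defaults: 9 999 permutations, recorded seed.

## Temporal clustering

The unfiltered count matrix is normalised by median-of-ratios size factors
(features positive in every sample; per-sample positive-feature fallback;
factors rescaled to geometric mean 1), `log1p`-transformed, linearly
detrended per vOTU over the chronological sample index, and Z-scaled.
Numerically constant residual profiles (e.g. exactly log-linear
trajectories) are dropped with a logged count. This normalise–detrend–scale
chain is a documented stand-in for the count-normalisation pipeline the
field uses, with each sub-step explicit, not a re-implementation of any
specific tool.

Clustering is PAM (BUILD then SWAP) on Euclidean distances between
Z-profiles; the objective is asserted non-increasing across swaps and the
procedure is deterministic. Model selection computes within-cluster SSE for
PAM and for Ward-linkage hierarchical partitions at every k in 1…20, takes
the elbow as the **knee point** — the k whose normalised SSE lies furthest
below the curve's end-to-end chord — cross-checked between the two curves,
and decides between the elbow k and its successor by average silhouette.
(The often-quoted "maximum second difference" elbow was evaluated and
rejected: whenever the data contain one dominant two-way split the 1→2 SSE
drop dwarfs all later drops and that rule degenerates to k = 2 even when a
finer partition is exact.)

Cluster profiles report the mean member Z-trajectory, and viral-family and
AMG-pathway totals (member relative abundance summed per family / per KEGG
pathway, weighted by AMG copy count) Z-scored **across clusters**, with
absent families/pathways flagged.

## Virus–host network

MAG quality is strict: high ⇔ completion > 90 and contamination < 5;
medium ⇔ completion > 50 and contamination < 10; anything else fails and is
excluded. Host predictions are kept only when the virus resolves to a
clustered vOTU (any member contig id, trimmed variants included) and the
host is a passing MAG; duplicate vOTU–MAG pairs collapse to the best score.
The order-level summary counts MAGs, vOTUs and total MAG relative abundance
per host order and lists vOTUs linked to more than one order, noting
whether the orders span phyla. The expectation that viral contigs were
removed from MAGs before host prediction is a documented precondition on
the MAG table, not an implemented step.

## Synthetic generator

The generator emulates the *statistical* structure the analysis assumes,
with one seeded random stream (fixed config ⇒ byte-identical outputs):

* Two sites × eight dates (the study's sampling months). Metadata columns
  are drawn from site-specific distributions whose means/SDs were estimated
  from the transcribed field table — normals for temperature (with a
  seasonal offset), DO, pH and salinity; mean-matched lognormals for the
  right-skewed nutrient and cell-count columns. The last date carries a
  sub-32 ppt salinity pulse at both sites; two winter dates are flagged
  post-freeze. The non-pulse salinity mean is inflated so the *overall*
  site mean matches the configured value.
* vOTUs as mutated copies (substitution-only, default divergence 0.02, so
  sibling identity ≈ 0.96) of independent random ancestors ≥ 10.5 kb, plus
  sub-10 kb viral contigs and non-viral decoys to exercise the filters.
* Temporal structure: each planted cluster owns a contiguous block of dates
  (orthogonal tile archetypes, small floor elsewhere) and a site mode —
  the freshwater cluster spans both sites and is amplified in the pulse
  samples; `site_overlap_fraction` sets the share of both-site clusters,
  the rest alternate sites; half of the site-specific vOTUs are displaced
  in the pulse sample. Site occupancy lives at cluster level because the
  real dynamic clusters of such surveys are themselves site-associated,
  and it keeps planted clusters internally coherent (recoverable by *any*
  correct method).
* Counts: negative binomial, dispersion 0.3 (over-Poisson noise typical of
  metagenomic counts), mean ∝ planted abundance × contig length × sample
  depth, split across members. Planted absences receive small stray
  background counts (mean 3 reads, breadth ≤ 0.5) emulating cross-mapping;
  they never flip detection, and they keep the count matrix well-posed for
  median-of-ratios normalisation. Detected cells get coverage intervals
  with breadth in (0.85, 0.98); absences stay at or below 0.75.
* Annotations: gene lineages match the vOTU's planted family at a 0.7
  majority, environments at 0.75; AMG pathways are enriched per planted
  cluster at 0.6; MAGs span the three quality classes; host predictions mix
  MAG and out-of-study reference targets and plant one multi-order virus.

What it does **not** emulate: read-level data, assembly artefacts, real
viral genome architecture (ancestors are i.i.d. uniform DNA; taxonomy comes
from annotation tables, not sequence content), strain micro-diversity,
multi-mapping ambiguity, or abiotic–community coupling beyond the
site/pulse structure. Passing recovery tests therefore demonstrates
correctness of the pipeline's logic under the stated noise model, not
performance on real reads.

## Problem sizes and runtime choices

Defaults in the test and acceptance runs: 60 vOTUs, 1–4 contigs each of
10.5–16 kb, 16 samples, 20 decoys; permutation tests at 199–999
permutations with seeds recorded; calibration at 500 null replicates with
199 permutations (with 199 permutations and the add-one rule the nominal
0.05 level is exactly achievable, p ∈ {1,…,10}/200). These sizes keep the
full suite and the acceptance script to a few minutes while leaving every
recovery margin wide.

## Known limitations

* The seeded ANI estimator needs an exact shared 15-mer to find a block;
  divergence approaching 7 % can fragment coverage. Within the vOTU regime
  (≥ 95 % identity) seeds are dense and this is immaterial.
* Greedy centroid clustering is order-dependent in principle; it matches
  all-pairs clustering only when clusters are separated well beyond the
  thresholds (as dereplicated viromes are in practice).
* The exhaustive ANOSIM enumerator is intended for small toy designs; the
  16-sample study designs always use the permutation path.
* NMDS minimises stress locally; 20 restarts from classical scaling have
  always reached stress < 0.1 on the synthetic designs but global
  optimality is not guaranteed.
* `bioenv` is exhaustive and bounded at 20 free variables without an
  explicit subset-size cap.
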
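"""Synthetic study generator with known ground truth.

Emulates the statistical structure of a two-site, eight-date hypersaline
estuary virome survey: two sites with partially disjoint viral communities,
temporal turnover organised in a small number of planted dynamic clusters,
one low-salinity freshwater-pulse sample per site, and two post-freeze
samples.  Every external pipeline input (contig FASTA, predictor-call table,
per-sample read counts and coverage intervals, gene taxonomy, AMG table,
host predictions, MAG table, sample metadata) is produced from a single
seeded random stream so a fixed :class:`SimConfig` yields byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from halovir import io as hio

NUCLEOTIDES = np.frombuffer(b"ACGT", dtype="S1")

#: the study's eight sampling months (first-of-month nominal dates)
STUDY_DATES = (
    "2020-05-01", "2020-06-01", "2020-09-01", "2020-10-01",
    "2021-01-01", "2021-02-01", "2021-03-01", "2021-06-01",
)

_SEASON_BY_MONTH = {12: "Winter", 1: "Winter", 2: "Winter", 3: "Spring",
                    4: "Spring", 5: "Spring", 6: "Summer", 7: "Summer",
                    8: "Summer", 9: "Fall", 10: "Fall", 11: "Fall"}
_TEMP_OFFSET = {"Spring": -1.5, "Summer": 4.0, "Fall": 2.5, "Winter": -5.0}

#: (realm, kingdom, phylum, class, order, family) reference lineages
LINEAGE_POOL = (
    ("Duplodnaviria", "Heunggongvirae", "Uroviricota", "Caudoviricetes", "Crassvirales", "Zobellviridae"),
    ("Duplodnaviria", "Heunggongvirae", "Uroviricota", "Caudoviricetes", "Crassvirales", "Schitoviridae"),
    ("Duplodnaviria", "Heunggongvirae", "Uroviricota", "Caudoviricetes", "Autographivirales", "Autographiviridae"),
    ("Duplodnaviria", "Heunggongvirae", "Uroviricota", "Caudoviricetes", "Kyanovirales", "Kyanoviridae"),
    ("Varidnaviria", "Bamfordvirae", "Nucleocytoviricota", "Megaviricetes", "Algavirales", "Phycodnaviridae"),
    ("Varidnaviria", "Bamfordvirae", "Preplasmiviricota", "Maveriviricetes", "Priklausovirales", "Lavidaviridae"),
    ("Varidnaviria", "Bamfordvirae", "Preplasmiviricota", "Tectiliviricetes", "Vinavirales", "Corticoviridae"),
)

ENVIRONMENTS = ("marine", "freshwater", "non-marine saline/alkaline", "unknown")

KEGG_POOL = (
    "Photosynthesis",
    "Oxidative phosphorylation",
    "Sulfur metabolism",
    "Carbon fixation pathways in prokaryotes",
    "Methane metabolism",
    "Nitrogen metabolism",
)

#: (domain, phylum, class, order) host lineages for MAGs
HOST_LINEAGES = (
    ("Bacteria", "Bacteroidota", "Bacteroidia", "Flavobacteriales"),
    ("Bacteria", "Bacteroidota", "Bacteroidia", "Chitinophagales"),
    ("Bacteria", "Bacteroidota", "Kapabacteria", "Kapabacteriales"),
    ("Bacteria", "Pseudomonadota", "Alphaproteobacteria", "Rhodobacterales"),
    ("Bacteria", "Pseudomonadota", "Gammaproteobacteria", "Chromatiales"),
    ("Bacteria", "Bdellovibrionota", "Bacteriovoracia", "Bacteriovoracales"),
    ("Bacteria", "Cyanobacteriota", "Cyanobacteriia", "PCC-6307"),
    ("Bacteria", "Actinomycetota", "Acidimicrobiia", "Actinomarinales"),
    ("Bacteria", "Deinococcota", "Deinococci", "Deinococcales"),
)

#: site-specific metadata means; salinity split into non-pulse / pulse parts
SITE_MEANS = {
    "LOC": {"temp_C": 26.05, "do_mg_per_L": 3.25, "pH": 8.24,
            "nh4_uM": 22.04, "no3_uM": 4.48, "no2_uM": 0.14,
            "autofluor_cells_per_mL": 470_000.0,
            "salinity_ppt": 61.66, "pulse_salinity_ppt": 2.6},
    "RB": {"temp_C": 24.61, "do_mg_per_L": 6.15, "pH": 8.14,
            "nh4_uM": 76.18, "no3_uM": 4.49, "no2_uM": 0.09,
            "autofluor_cells_per_mL": 38_125.0,
            "salinity_ppt": 43.72, "pulse_salinity_ppt": 16.0},
}
SITE_SDS = {"temp_C": 3.0, "do_mg_per_L": 1.2, "pH": 0.25, "salinity_ppt": 2.5,
            "pulse_salinity_ppt": 1.5}
#: lognormal sigma for strictly positive, right-skewed columns
LOGNORMAL_SIGMA = {"nh4_uM": 0.8, "no3_uM": 0.6, "no2_uM": 0.9,
                   "autofluor_cells_per_mL": 1.2}


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study; defaults are the emulated design."""

    seed: int = 0
    sites: tuple[str, str] = ("LOC", "RB")
    n_dates: int = 8
    n_votus: int = 60
    contigs_per_votu: tuple[int, int] = (1, 4)
    contig_length_range: tuple[int, int] = (10_500, 16_000)
    #: extra true-viral contigs below 10 kb, per planted vOTU count
    short_viral_fraction: float = 0.10
    n_decoys: int = 20
    within_votu_divergence: float = 0.02
    between_votu_divergence: float = 0.50  # ancestors are independent draws
    site_overlap_fraction: float = 0.30
    n_planted_temporal_clusters: int = 5
    predictors: tuple[str, ...] = ("vibrant", "virsorter2", "checkv", "genomad")
    predictor_sensitivity: tuple[float, ...] = (0.95, 0.95, 0.95, 0.95)
    predictor_fpr: tuple[float, ...] = (0.02, 0.02, 0.02, 0.02)
    trimmed_call_fraction: float = 0.15
    trim_delimiter: str = "||"
    #: negative-binomial dispersion (var = mu + phi mu^2)
    dispersion: float = 0.3
    mean_depth_reads: int = 2_000_000
    disturbance_effects: tuple[float, float] = (4.0, 4.0)  # pulse, freeze
    pulse_swap_fraction: float = 0.5
    detected_breadth_range: tuple[float, float] = (0.85, 0.98)
    #: fraction of absent (vOTU, sample) cells given stray sub-threshold reads
    #: (cross-mapping background; keeps every sample positive for most vOTUs
    #: so median-of-ratios normalisation is well-posed)
    stray_signal_fraction: float = 1.0
    stray_mean_reads: float = 3.0
    genes_per_contig: tuple[int, int] = (8, 16)
    taxonomy_majority_fraction: float = 0.7
    environment_majority_fraction: float = 0.75
    amg_enrichment: float = 0.6
    amg_mean_per_votu: float = 2.0
    n_mags: int = 30
    host_votu_fraction: float = 0.35
    nonmag_prediction_fraction: float = 0.2
    n_multi_order_votus: int = 1
    lineage_pool: tuple = LINEAGE_POOL
    kegg_pool: tuple[str, ...] = KEGG_POOL

    @property
    def n_samples(self) -> int:
        return len(self.sites) * self.n_dates

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_dates <= 0:
            raise SimConfigError("need a positive number of samples")
        if len(self.sites) != 2:
            raise SimConfigError("exactly two site labels required")
        if self.contig_length_range[0] < 1:
            raise SimConfigError("contig lengths must be positive")
        if not 0.0 < self.within_votu_divergence < 0.05:
            raise SimConfigError("within_votu_divergence must lie in (0, 0.05)")
        if len(self.predictor_sensitivity) != len(self.predictors) or \
                len(self.predictor_fpr) != len(self.predictors):
            raise SimConfigError("per-predictor probability vectors must match predictors")
        for p in (*self.predictor_sensitivity, *self.predictor_fpr):
            if not 0.0 <= p <= 1.0:
                raise SimConfigError(f"predictor probability {p} outside [0, 1]")
        if not self.lineage_pool:
            raise SimConfigError("lineage pool must be non-empty")
        if self.n_planted_temporal_clusters < 1:
            raise SimConfigError("need at least one planted temporal cluster")


@dataclass
class GroundTruth:
    """Planted structure recoverable by the pipeline."""

    votu_assignment: dict[str, str]        # contig id -> planted vOTU id
    viral_flag: dict[str, bool]            # contig id -> is a true virus
    temporal_cluster: dict[str, str]       # vOTU id -> planted cluster id
    true_abundance: pd.DataFrame           # vOTU x sample expected abundance
    presence: pd.DataFrame                 # vOTU x sample planted presence
    site_class: dict[str, str]             # vOTU id -> LOC-only / RB-only / both
    environment: dict[str, str]            # vOTU id -> planted source environment
    family: dict[str, str]                 # vOTU id -> planted viral family
    enriched_pathway: dict[str, str]       # planted cluster id -> enriched KEGG pathway
    sample_ids: list[str]
    representative_hint: dict[str, str] = field(default_factory=dict)


@dataclass
class SimulatedDataset:
    """All pipeline inputs plus their generating truth."""

    config: SimConfig
    metadata: pd.DataFrame
    contigs: dict[str, str]
    truth: GroundTruth
    predictor_calls: pd.DataFrame
    read_counts: pd.DataFrame
    coverage: pd.DataFrame
    sample_depths: pd.DataFrame
    gene_taxonomy: pd.DataFrame
    amg: pd.DataFrame
    host_predictions: pd.DataFrame
    mags: pd.DataFrame


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _dates(config: SimConfig) -> list[str]:
    if config.n_dates == 8:
        return list(STUDY_DATES)
    # otherwise a monthly sequence starting at the study's first month
    start = datetime.date(2020, 5, 1)
    out = []
    y, m = start.year, start.month
    for _ in range(config.n_dates):
        out.append(f"{y:04d}-{m:02d}-01")
        m += 1
        if m > 12:
            m, y = 1, y + 1
    return out


def _pulse_and_freeze(dates: list[str]) -> tuple[str, list[str]]:
    """The pulse date (last) and up to two freeze-aftermath dates before it."""
    pulse = dates[-1]
    n = len(dates)
    freeze = [dates[i] for i in range(max(0, n - 4), n - 2)] if n >= 3 else []
    return pulse, freeze


def sample_order(config: SimConfig) -> list[str]:
    """Samples ordered chronologically within site: all LOC dates, then RB."""
    return [f"{site}_{d}" for site in config.sites for d in _dates(config)]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(NUCLEOTIDES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    n_mut = rng.binomial(len(arr), rate)
    if n_mut:
        pos = rng.choice(len(arr), size=n_mut, replace=False)
        # substitute with a *different* base: shift 1..3 positions in ACGT
        idx = np.searchsorted(NUCLEOTIDES, arr[pos])
        arr[pos] = NUCLEOTIDES[(idx + rng.integers(1, 4, size=n_mut)) % 4]
    return arr.tobytes().decode()


def _negbin(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    n = 1.0 / dispersion
    p = n / (n + mean[pos])
    out[pos] = rng.negative_binomial(n, p)
    return out


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_metadata(config: SimConfig) -> pd.DataFrame:
    """One metadata row per site-date drawn from site-specific distributions.

    Exactly one date per site (the last) carries a sub-32 ppt salinity pulse;
    the two dates preceding the penultimate one are flagged as post-freeze.
    Normal draws are used for temperature/DO/pH/salinity (with a seasonal
    temperature offset) and mean-matched lognormal draws for the skewed,
    strictly-positive nutrient and cell-count columns.
    """
    rng = np.random.default_rng(config.seed)
    dates = _dates(config)
    pulse_date, freeze_dates = _pulse_and_freeze(dates)
    rows = []
    for site in config.sites:
        means = SITE_MEANS.get(site, SITE_MEANS["LOC"])
        for d in dates:
            season = _SEASON_BY_MONTH[int(d[5:7])]
            row = {"site": site, "date": d, "season": season}
            row["temp_C"] = rng.normal(means["temp_C"] + _TEMP_OFFSET[season],
                                       SITE_SDS["temp_C"])
            row["do_mg_per_L"] = max(0.1, rng.normal(means["do_mg_per_L"],
                                                     SITE_SDS["do_mg_per_L"]))
            if d == pulse_date:
                sal = rng.normal(means["pulse_salinity_ppt"], SITE_SDS["pulse_salinity_ppt"])
                row["salinity_ppt"] = float(np.clip(sal, 0.1, 31.9))
            else:
                # expected overall mean matches the configured site mean
                n = len(dates)
                nonpulse_mean = (n * means["salinity_ppt"] - means["pulse_salinity_ppt"]) / (n - 1) \
                    if n > 1 else means["salinity_ppt"]
                row["salinity_ppt"] = float(np.clip(
                    rng.normal(nonpulse_mean, SITE_SDS["salinity_ppt"]), 32.1, None))
            row["pH"] = rng.normal(means["pH"], SITE_SDS["pH"])
            for col, sigma in LOGNORMAL_SIGMA.items():
                mu = math.log(max(means[col], 1e-6)) - sigma ** 2 / 2
                row[col] = float(rng.lognormal(mu, sigma))
            row["is_pulse"] = int(d == pulse_date)
            row["is_freeze"] = int(d in freeze_dates)
            rows.append(row)
    cols = list(hio.TABLE_SCHEMAS["metadata"])
    return pd.DataFrame(rows)[cols]


def metadata_header_comments(config: SimConfig) -> list[str]:
    out = ["synthetic site-month abiotic conditions; site-specific draw parameters:"]
    for site in config.sites:
        means = SITE_MEANS.get(site, SITE_MEANS["LOC"])
        out.append(f"{site} means: " + ", ".join(f"{k}={v}" for k, v in means.items()))
    out.append("normal SDs: " + ", ".join(f"{k}={v}" for k, v in SITE_SDS.items()))
    out.append("lognormal sigmas: " + ", ".join(f"{k}={v}" for k, v in LOGNORMAL_SIGMA.items()))
    return out


def _cluster_site_modes(config: SimConfig, fresh_cluster: int) -> list[str]:
    """Site occupancy per planted cluster.

    Dynamic clusters are site-associated, the way real estuary virome
    clusters are (a cluster typical of one salinity regime, a shared
    freshwater-pulse cluster, ...): the freshwater cluster spans both
    sites, ``site_overlap_fraction`` sets the total share of both-site
    clusters, and the remaining clusters alternate between the two sites.
    """
    K = config.n_planted_temporal_clusters
    n_both = min(K, max(1, round(config.site_overlap_fraction * K)))
    modes = [""] * K
    modes[fresh_cluster] = "both"
    remaining = [k for k in range(K) if k != fresh_cluster]
    for k in remaining[: n_both - 1]:
        modes[k] = "both"
    toggle = 0
    for k in remaining[n_both - 1:]:
        modes[k] = f"{config.sites[toggle % 2]}-only"
        toggle += 1
    return modes


def _plant_structure(config: SimConfig, rng: np.random.Generator):
    """Plant vOTU site classes, temporal clusters, and expected abundances.

    Each cluster has a smooth bump archetype over the date axis (bump
    nearest the pulse date = the freshwater cluster) and a site mode; a
    vOTU inherits both from its cluster, so planted clusters are coherent
    over the full two-site sample axis.
    """
    dates = _dates(config)
    pulse_date, freeze_dates = _pulse_and_freeze(dates)
    samples = sample_order(config)
    K = config.n_planted_temporal_clusters
    n = config.n_votus
    votu_ids = [f"tv{i:04d}" for i in range(n)]

    # orthogonal date-tile archetypes: cluster k is elevated in its own
    # contiguous block of dates and at a small floor elsewhere, so planted
    # clusters are near-equidistant in profile space
    seg = np.floor(np.arange(len(dates)) * K / len(dates)).astype(int)
    arche = np.where(seg[None, :] == np.arange(K)[:, None], 1.0, 0.0) + 0.05
    fresh_cluster = int(seg[-1])
    freeze_idx = int(round(np.mean([dates.index(d) for d in freeze_dates]))) \
        if freeze_dates else max(0, len(dates) - 3)
    freeze_cluster = int(seg[freeze_idx])
    modes = _cluster_site_modes(config, fresh_cluster)

    # even-sized clusters with randomised membership
    perm = rng.permutation(n)
    cluster_of = {votu_ids[perm[i]]: f"cl{i % K}" for i in range(n)}
    site_class = {v: modes[int(cluster_of[v][2:])] for v in votu_ids}

    pulse_mult, freeze_mult = config.disturbance_effects
    base = rng.lognormal(math.log(30.0), 0.7, size=n)
    abund = pd.DataFrame(0.0, index=votu_ids, columns=samples)
    # site-specific vOTUs displaced by the freshwater pulse
    swapped = {v for v in votu_ids
               if site_class[v] != "both" and rng.random() < config.pulse_swap_fraction}
    for vi, v in enumerate(votu_ids):
        k = int(cluster_of[v][2:])
        for site in config.sites:
            allowed = site_class[v] == "both" or site_class[v].startswith(site)
            if not allowed:
                continue
            for di, d in enumerate(dates):
                s = f"{site}_{d}"
                if d == pulse_date:
                    if k == fresh_cluster:
                        abund.loc[v, s] = base[vi] * arche[k, di] * pulse_mult
                    elif v not in swapped:
                        abund.loc[v, s] = base[vi] * arche[k, di]
                else:
                    mult = freeze_mult if (k == freeze_cluster and d in freeze_dates) else 1.0
                    abund.loc[v, s] = base[vi] * arche[k, di] * mult
    presence = abund > 0
    return votu_ids, cluster_of, site_class, abund, presence


def generate_contigs(config: SimConfig) -> tuple[dict[str, str], GroundTruth]:
    """Mutated vOTU member contigs plus short viral contigs and decoys.

    Contig ids encode the sample of origin (``<site>_<date>_c<serial>``).
    Members of one planted vOTU are independently mutated copies of a shared
    random ancestor, so sibling identity is about ``1 - 2 d`` for divergence
    ``d``; ancestors of different vOTUs are independent sequences with no
    alignable homology.
    """
    rng = np.random.default_rng(config.seed + 1)
    votu_ids, cluster_of, site_class, abund, presence = _plant_structure(config, rng)
    samples = sample_order(config)
    lo, hi = config.contig_length_range
    if lo < 1:
        raise SimConfigError("contig lengths must be positive")

    contigs: dict[str, str] = {}
    assignment: dict[str, str] = {}
    viral: dict[str, bool] = {}
    rep_hint: dict[str, str] = {}
    serial = 0

    def new_id(sample: str) -> str:
        nonlocal serial
        serial += 1
        return f"{sample}_c{serial:05d}"

    for v in votu_ids:
        ancestor = _random_sequence(rng, int(rng.integers(lo, hi + 1)))
        n_members = int(rng.integers(config.contigs_per_votu[0],
                                     config.contigs_per_votu[1] + 1))
        present_samples = [s for s in samples if presence.loc[v, s]]
        if not present_samples:
            present_samples = [samples[0]]
        longest = None
        for _ in range(n_members):
            s = present_samples[int(rng.integers(len(present_samples)))]
            cid = new_id(s)
            contigs[cid] = _mutate(rng, ancestor, config.within_votu_divergence)
            assignment[cid] = v
            viral[cid] = True
            if longest is None:
                longest = cid
        rep_hint[v] = longest

    n_short = int(round(config.short_viral_fraction * config.n_votus))
    for i in range(n_short):
        s = samples[int(rng.integers(len(samples)))]
        cid = new_id(s)
        contigs[cid] = _random_sequence(rng, int(rng.integers(3_000, 9_500)))
        assignment[cid] = f"sv{i:04d}"
        viral[cid] = True

    for i in range(config.n_decoys):
        s = samples[int(rng.integers(len(samples)))]
        cid = new_id(s)
        length = int(rng.integers(4_000, hi + 1))
        contigs[cid] = _random_sequence(rng, length)
        assignment[cid] = f"nv{i:04d}"
        viral[cid] = False

    rng2 = np.random.default_rng(config.seed + 2)
    families = {v: config.lineage_pool[int(rng2.integers(len(config.lineage_pool)))][-1]
                for v in votu_ids}
    env_of = {}
    for v in votu_ids:
        sc = site_class[v]
        if cluster_of[v] == _freshwater_cluster_id(config):
            env_of[v] = "freshwater"
        elif sc.endswith("-only") and sc.startswith(config.sites[0]):
            env_of[v] = "non-marine saline/alkaline"
        elif sc.endswith("-only"):
            env_of[v] = "marine"
        else:
            env_of[v] = "marine" if rng2.random() < 0.6 else "unknown"

    K = config.n_planted_temporal_clusters
    enriched = {f"cl{k}": config.kegg_pool[k % len(config.kegg_pool)] for k in range(K)}

    truth = GroundTruth(
        votu_assignment=assignment, viral_flag=viral,
        temporal_cluster=cluster_of, true_abundance=abund, presence=presence,
        site_class=site_class, environment=env_of, family=families,
        enriched_pathway=enriched, sample_ids=samples,
        representative_hint=rep_hint,
    )
    return contigs, truth


def _freshwater_cluster_id(config: SimConfig) -> str:
    t_last = config.n_dates - 1
    centers = np.linspace(0, t_last, config.n_planted_temporal_clusters)
    return f"cl{int(np.argmin(np.abs(centers - t_last)))}"


def generate_predictor_calls(contigs: dict[str, str], truth: GroundTruth,
                             config: SimConfig) -> pd.DataFrame:
    """Per-predictor viral calls with optional provirus-style trimmed variants.

    A trimmed variant reuses the base contig name plus a
    ``<delim><start>_<end>`` coordinate suffix (0-based half-open), the way
    provirus-trimming tools emit boundary-clipped duplicates.
    """
    rng = np.random.default_rng(config.seed + 3)
    sens = dict(zip(config.predictors, config.predictor_sensitivity))
    fpr = dict(zip(config.predictors, config.predictor_fpr))
    rows = []
    for cid, seq in contigs.items():
        L = len(seq)
        for p in config.predictors:
            prob = sens[p] if truth.viral_flag[cid] else fpr[p]
            if rng.random() >= prob:
                continue
            if L > 10_800 and rng.random() < config.trimmed_call_fraction:
                # clip one end but stay comfortably above the length filter
                tlen = max(int(L * rng.uniform(0.80, 0.95)), min(L - 1, 10_500))
                start = int(rng.integers(0, L - tlen + 1))
                rows.append({"contig_id": f"{cid}{config.trim_delimiter}{start}_{start + tlen}",
                             "predictor": p, "called_length_bp": tlen})
            else:
                rows.append({"contig_id": cid, "predictor": p, "called_length_bp": L})
    return pd.DataFrame(rows, columns=list(hio.TABLE_SCHEMAS["predictor_calls"]))


def generate_alignments(contigs: dict[str, str], truth: GroundTruth,
                        config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read-count, coverage-interval and sample-depth tables.

    Counts follow a negative binomial with mean proportional to planted
    abundance x contig length x sample depth, split evenly across a vOTU's
    member contigs.  Coverage intervals give detected cells breadth above
    0.75 and planted absences breadth at or below it (0 by default).
    """
    rng = np.random.default_rng(config.seed + 4)
    samples = truth.sample_ids
    depths = {s: int(config.mean_depth_reads * rng.lognormal(0, 0.2)) for s in samples}

    members: dict[str, list[str]] = {}
    for cid, v in truth.votu_assignment.items():
        members.setdefault(v, []).append(cid)

    count_rows, cov_rows = [], []
    b_lo, b_hi = config.detected_breadth_range
    for v in truth.true_abundance.index:
        mem = members.get(v, [])
        for s in samples:
            a = truth.true_abundance.loc[v, s]
            present = bool(truth.presence.loc[v, s])
            for cid in mem:
                L = len(contigs[cid])
                if present and a > 0:
                    mu = a * (L / 1000.0) * (depths[s] / 1e6) / len(mem)
                    c = int(_negbin(rng, np.array([mu]), config.dispersion)[0])
                    c = max(c, 1)  # a planted presence is never lost to noise
                    count_rows.append({"sample_id": s, "contig_id": cid, "reads": c})
                    breadth = rng.uniform(b_lo, b_hi)
                    cov_rows.extend(_intervals_for(rng, L, breadth, s, cid))
                elif config.stray_signal_fraction and rng.random() < config.stray_signal_fraction:
                    c = int(_negbin(rng, np.array([config.stray_mean_reads]),
                                    config.dispersion)[0])
                    count_rows.append({"sample_id": s, "contig_id": cid,
                                       "reads": max(c, 1)})
                    cov_rows.extend(_intervals_for(rng, L, rng.uniform(0.05, 0.5), s, cid))
    # decoys and short viral contigs: sparse background signal
    extras = [c for c, v in truth.votu_assignment.items()
              if v.startswith(("nv", "sv"))]
    for cid in extras:
        L = len(contigs[cid])
        for s in samples:
            if rng.random() < 0.25:
                count_rows.append({"sample_id": s, "contig_id": cid,
                                   "reads": int(rng.integers(1, 200))})
                cov_rows.extend(_intervals_for(rng, L, rng.uniform(0.3, 0.97), s, cid))

    counts = pd.DataFrame(count_rows, columns=list(hio.TABLE_SCHEMAS["read_counts"]))
    coverage = pd.DataFrame(cov_rows, columns=list(hio.TABLE_SCHEMAS["coverage"]))
    depth_df = pd.DataFrame({"sample_id": samples,
                             "total_reads": [depths[s] for s in samples]})
    return counts, coverage, depth_df


def _intervals_for(rng: np.random.Generator, length: int, breadth: float,
                   sample_id: str, contig_id: str) -> list[dict]:
    """Two disjoint intervals whose union length is round(breadth * length)."""
    covered = int(round(breadth * length))
    covered = min(covered, length)
    if covered <= 0:
        return []
    if covered == length:
        return [{"sample_id": sample_id, "contig_id": contig_id, "start": 0, "end": length}]
    first = int(rng.integers(1, covered + 1))
    second = covered - first
    gap_total = length - covered
    gap = int(rng.integers(1, gap_total + 1))
    out = [{"sample_id": sample_id, "contig_id": contig_id, "start": 0, "end": first}]
    if second > 0 and first + gap + second <= length:
        out.append({"sample_id": sample_id, "contig_id": contig_id,
                    "start": first + gap, "end": first + gap + second})
    elif second > 0:
        out.append({"sample_id": sample_id, "contig_id": contig_id,
                    "start": length - second, "end": length})
    return out


def generate_annotations_and_hosts(truth: GroundTruth, config: SimConfig
                                   ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene taxonomy, AMG, host-prediction and MAG tables.

    Gene lineages agree with the vOTU's planted family at the configured
    majority fraction; AMG pathways are enriched per planted temporal
    cluster; host predictions mix MAG targets with out-of-study reference
    genomes to exercise the MAG-only filter.
    """
    if not config.lineage_pool:
        raise SimConfigError("lineage pool must be non-empty")
    rng = np.random.default_rng(config.seed + 5)
    lineage_by_family = {lin[-1]: lin for lin in config.lineage_pool}

    gene_rows, amg_rows = [], []
    votu_members: dict[str, list[str]] = {}
    for cid, v in truth.votu_assignment.items():
        if truth.viral_flag[cid] and v in truth.family:
            votu_members.setdefault(v, []).append(cid)

    for v, mem in votu_members.items():
        true_lin = lineage_by_family[truth.family[v]]
        true_env = truth.environment[v]
        for cid in mem:
            n_genes = int(rng.integers(config.genes_per_contig[0],
                                       config.genes_per_contig[1] + 1))
            for g in range(n_genes):
                if rng.random() < config.taxonomy_majority_fraction:
                    lin = true_lin
                else:
                    lin = config.lineage_pool[int(rng.integers(len(config.lineage_pool)))]
                if rng.random() < config.environment_majority_fraction:
                    env = true_env
                else:
                    env = ENVIRONMENTS[int(rng.integers(len(ENVIRONMENTS)))]
                gene_rows.append({
                    "contig_id": cid, "gene_id": f"{cid}_g{g:03d}",
                    "realm": lin[0], "kingdom": lin[1], "phylum": lin[2],
                    "class": lin[3], "order": lin[4], "family": lin[5],
                    "environment": env if env != "unknown" else "",
                })
        # AMGs live on the representative-sized first member
        enriched = truth.enriched_pathway[truth.temporal_cluster[v]]
        others = [p for p in config.kegg_pool if p != enriched]
        n_amg = int(rng.poisson(config.amg_mean_per_votu))
        for g in range(n_amg):
            path = enriched if rng.random() < config.amg_enrichment \
                else others[int(rng.integers(len(others)))]
            amg_rows.append({"contig_id": mem[0], "gene_id": f"{mem[0]}_amg{g:02d}",
                             "kegg_pathway": path})

    # MAGs spanning the three quality classes
    mag_rows = []
    for i in range(config.n_mags):
        u = rng.random()
        if u < 0.55:
            comp, cont = rng.uniform(91, 99.5), rng.uniform(0, 4.9)
        elif u < 0.85:
            comp, cont = rng.uniform(51, 90), rng.uniform(0, 9.9)
        else:
            comp, cont = rng.uniform(20, 50), rng.uniform(0, 20)
        host = HOST_LINEAGES[int(rng.integers(len(HOST_LINEAGES)))]
        mag_rows.append({
            "mag_id": f"mag{i:03d}", "completion": round(comp, 2),
            "contamination": round(cont, 2), "domain": host[0],
            "phylum": host[1], "class": host[2], "order": host[3],
            "length_bp": int(rng.integers(1_800_000, 5_200_000)),
            "relative_abundance": float(rng.lognormal(0, 1)),
        })
    mags = pd.DataFrame(mag_rows, columns=list(hio.TABLE_SCHEMAS["mags"]))
    good = mags[(mags.completion > 50) & (mags.contamination < 10)]

    host_rows = []
    votus = sorted(votu_members)
    n_hosted = int(round(config.host_votu_fraction * len(votus)))
    hosted = list(rng.choice(votus, size=min(n_hosted, len(votus)), replace=False))
    for v in hosted:
        virus_id = votu_members[v][0]
        if rng.random() < config.nonmag_prediction_fraction or good.empty:
            target = f"refgenome{int(rng.integers(10_000)):05d}"
        else:
            target = good.mag_id.iloc[int(rng.integers(len(good)))]
        host_rows.append({"virus_id": virus_id, "host_genome": target,
                          "score": round(rng.uniform(75, 100), 2)})
    # plant multi-order viruses: extra links to a MAG of a different order
    if not good.empty:
        by_order = good.groupby("order").mag_id.first()
        for v in hosted[: config.n_multi_order_votus]:
            if len(by_order) >= 2:
                host_rows.append({"virus_id": votu_members[v][0],
                                  "host_genome": by_order.iloc[0], "score": 95.0})
                host_rows.append({"virus_id": votu_members[v][0],
                                  "host_genome": by_order.iloc[1], "score": 92.0})
    hosts = pd.DataFrame(host_rows, columns=list(hio.TABLE_SCHEMAS["host_predictions"]))
    genes = pd.DataFrame(gene_rows, columns=list(hio.TABLE_SCHEMAS["gene_taxonomy"]))
    amg = pd.DataFrame(amg_rows, columns=list(hio.TABLE_SCHEMAS["amg"]))
    return genes, amg, hosts, mags


# ---------------------------------------------------------------------------
# one-call dataset
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig | None = None) -> SimulatedDataset:
    """Generate every pipeline input from a single configuration."""
    config = config or SimConfig()
    metadata = generate_metadata(config)
    contigs, truth = generate_contigs(config)
    calls = generate_predictor_calls(contigs, truth, config)
    counts, coverage, depths = generate_alignments(contigs, truth, config)
    genes, amg, hosts, mags = generate_annotations_and_hosts(truth, config)
    return SimulatedDataset(config, metadata, contigs, truth, calls,
                            counts, coverage, depths, genes, amg, hosts, mags)


def write_fixture(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write a complete fixture directory plus ground-truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dataset.config
    hio.write_fasta(dataset.contigs, outdir / "contigs.fasta")
    hio.write_table(dataset.metadata, outdir / "metadata.tsv",
                    metadata_header_comments(cfg))
    hio.write_table(dataset.predictor_calls, outdir / "predictor_calls.tsv")
    hio.write_table(dataset.read_counts, outdir / "read_counts.tsv")
    hio.write_table(dataset.coverage, outdir / "coverage.tsv")
    hio.write_table(dataset.sample_depths, outdir / "sample_depths.tsv")
    hio.write_table(dataset.gene_taxonomy, outdir / "gene_taxonomy.tsv")
    hio.write_table(dataset.amg, outdir / "amg.tsv")
    hio.write_table(dataset.host_predictions, outdir / "host_predictions.tsv")
    hio.write_table(dataset.mags, outdir / "mags.tsv")
    truth = dataset.truth
    assign = pd.DataFrame({
        "contig_id": list(truth.votu_assignment),
        "votu_id": list(truth.votu_assignment.values()),
        "viral": [int(truth.viral_flag[c]) for c in truth.votu_assignment],
    })
    hio.write_table(assign, outdir / "truth_votu_assignment.tsv")
    clusters = pd.DataFrame({"votu_id": list(truth.temporal_cluster),
                             "cluster_id": list(truth.temporal_cluster.values())})
    hio.write_table(clusters, outdir / "truth_temporal_cluster.tsv")
    hio.write_table(truth.true_abundance.rename_axis("votu_id").reset_index(),
                    outdir / "truth_abundance.tsv")
    cfg_json = {f.name: getattr(cfg, f.name) for f in dataclasses.fields(cfg)
                if f.name not in ("lineage_pool",)}
    (outdir / "sim_config.json").write_text(
        pd.Series(cfg_json, dtype=object).to_json(indent=2))
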
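"""Temporal clustering of vOTU abundance dynamics.

Raw (unfiltered) vOTU read counts are normalised with median-of-ratios size
factors, log-transformed, linearly detrended per vOTU over the chronological
sample order and standardised to Z-scores; the Z-profiles are then clustered
with PAM k-medoids.  The number of clusters is selected by locating the
elbow (maximum second difference) of the within-cluster SSE curve — computed
for both PAM and a Ward-linkage hierarchical comparator — and comparing
average silhouettes in the elbow neighbourhood.  Each final cluster is
profiled by its mean Z trajectory and by viral-family and AMG KEGG-pathway
abundance Z-scores across clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.metrics import silhouette_score

logger = logging.getLogger("halovir")


@dataclass
class ZProfile:
    votu_id: str
    values: np.ndarray  # per-sample Z-scores of normalised, detrended counts


@dataclass
class ClusterModel:
    k: int
    medoids: list[str]
    assignment: dict[str, int]          # vOTU id -> cluster index (0-based)
    sse_by_k: dict[str, dict[int, float]]       # method -> k -> within SSE
    silhouette_by_k: dict[int, float]
    chosen_k: int
    seed: int
    candidate_ks: tuple[int, ...] = ()

    def labels(self, ids: list[str]) -> np.ndarray:
        return np.asarray([self.assignment[i] for i in ids])


@dataclass
class ClusterProfile:
    cluster: int
    mean_trajectory: pd.Series          # per-sample mean Z
    family_z: pd.Series                 # per-family Z across clusters
    pathway_z: pd.Series                # per-KEGG-pathway Z across clusters
    absent_families: tuple[str, ...] = ()
    absent_pathways: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, one positive scalar per sample column.

    Ratios are count over per-feature geometric mean, restricted to features
    positive in every sample; when no feature qualifies each sample falls
    back to the median ratio over its own positive features.  Factors are
    rescaled to geometric mean 1.
    """
    X = counts.values.astype(float)
    if (X.sum(axis=0) == 0).any():
        bad = counts.columns[X.sum(axis=0) == 0].tolist()
        raise ValueError(f"samples with all-zero counts: {bad}")
    everywhere = (X > 0).all(axis=1)
    with np.errstate(divide="ignore"):
        logX = np.where(X > 0, np.log(X), np.nan)
    factors = np.empty(X.shape[1])
    if everywhere.any():
        geo = logX[everywhere].mean(axis=1, keepdims=True)
        ratios = logX[everywhere] - geo
        factors = np.exp(np.median(ratios, axis=0))
    else:
        geo = np.nanmean(logX, axis=1, keepdims=True)
        ratios = logX - geo
        factors = np.exp(np.nanmedian(ratios, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


def normalize_detrend_scale(counts: pd.DataFrame, sample_order: list[str] | None = None,
                            constant_tol: float = 1e-9) -> list[ZProfile]:
    """Counts -> size-factor normalisation -> log1p -> linear detrend -> Z.

    ``sample_order`` must list the count columns chronologically within
    site; the least-squares linear trend over the sample index is removed
    per vOTU and the residuals standardised to mean 0 / SD 1.  Profiles
    whose residuals are (numerically) constant — e.g. exactly linear
    trajectories — are dropped with a logged count.
    """
    if sample_order is not None:
        counts = counts[sample_order]
    if counts.shape[1] < 3:
        raise ValueError("need at least 3 samples to detrend")
    sf = size_factors(counts)
    norm = np.log1p(counts.values / sf.values[None, :])
    t = np.arange(counts.shape[1], dtype=float)
    # least-squares linear fit per row, vectorised
    t_c = t - t.mean()
    slope = (norm - norm.mean(axis=1, keepdims=True)) @ t_c / (t_c @ t_c)
    resid = norm - norm.mean(axis=1, keepdims=True) - slope[:, None] * t_c[None, :]
    sd = resid.std(axis=1)
    profiles = []
    dropped = 0
    for i, votu in enumerate(counts.index):
        if sd[i] <= constant_tol:
            dropped += 1
            continue
        profiles.append(ZProfile(str(votu), (resid[i] - resid[i].mean()) / sd[i]))
    if dropped:
        logger.info("normalize_detrend_scale: dropped %d constant profiles", dropped)
    return profiles


# ---------------------------------------------------------------------------
# PAM k-medoids
# ---------------------------------------------------------------------------

def _pam(dist: np.ndarray, k: int, max_swaps: int = 200) -> tuple[list[int], np.ndarray]:
    """PAM BUILD + SWAP on a precomputed distance matrix.

    Deterministic; the total distance to medoids never increases across
    SWAP steps (asserted).  Returns (medoid indices, assignment).
    """
    n = dist.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}]")
    # BUILD: first medoid minimises total distance, then greedy gain
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    nearest = dist[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.maximum(nearest[None, :] - dist, 0).sum(axis=1)
        gains[medoids] = -1
        new = int(np.argmax(gains))
        medoids.append(new)
        nearest = np.minimum(nearest, dist[new])

    def cost(meds: list[int]) -> float:
        return float(dist[meds].min(axis=0).sum())

    current = cost(medoids)
    for _ in range(max_swaps):
        best_delta, best_swap = -1e-12, None
        med_set = set(medoids)
        for mi, m in enumerate(medoids):
            others = [x for x in medoids if x != m]
            base = dist[others].min(axis=0) if others else np.full(n, np.inf)
            for h in range(n):
                if h in med_set:
                    continue
                new_cost = float(np.minimum(base, dist[h]).sum())
                delta = current - new_cost
                if delta > best_delta:
                    best_delta, best_swap = delta, (mi, h, new_cost)
        if best_swap is None:
            break
        mi, h, new_cost = best_swap
        assert new_cost <= current + 1e-9, "PAM objective increased"
        medoids[mi] = h
        current = new_cost
    assignment = np.argmin(dist[medoids], axis=0)
    # medoids always assign to themselves even under distance ties
    for ci, m in enumerate(medoids):
        assignment[m] = ci
    return medoids, assignment


def kmedoids(profiles: list[ZProfile], k: int, seed: int = 0
             ) -> tuple[list[str], dict[str, int]]:
    """PAM partition of Z-profiles under Euclidean distance.

    Deterministic given the input order (the seed is recorded for interface
    parity; PAM BUILD/SWAP has no stochastic step).
    """
    if k > len(profiles):
        raise ValueError(f"k={k} exceeds {len(profiles)} profiles")
    ids = [p.votu_id for p in profiles]
    X = np.vstack([p.values for p in profiles])
    dist = squareform(pdist(X))
    medoid_idx, assignment = _pam(dist, k)
    return [ids[m] for m in medoid_idx], {i: int(c) for i, c in zip(ids, assignment)}


def _within_sse(dist_sq: np.ndarray, medoids: list[int], assignment: np.ndarray) -> float:
    return float(sum(dist_sq[m, assignment == ci].sum()
                     for ci, m in enumerate(medoids)))


def _knee(sse: dict[int, float]) -> int:
    """k whose (normalised) SSE lies furthest below the end-to-end chord."""
    ks = sorted(sse)
    y = np.asarray([sse[k] for k in ks], dtype=float)
    if len(ks) < 3 or y[0] == y[-1]:
        return ks[0]
    yn = (y - y[-1]) / (y[0] - y[-1])
    xn = (np.asarray(ks, dtype=float) - ks[0]) / (ks[-1] - ks[0])
    return ks[int(np.argmax((1 - xn) - yn))]


def select_k(profiles: list[ZProfile], k_range: range | None = None,
             seed: int = 0) -> ClusterModel:
    """Model selection for the number of temporal clusters.

    Computes within-cluster SSE (squared distance to the cluster centre:
    the medoid for PAM, confirmed against Ward-linkage hierarchical
    partitions at every k), locates the steepest-decline elbow of the PAM
    curve as the knee point (furthest below the SSE curve's end-to-end
    chord), then compares average silhouettes at the elbow k and its
    successor; the final k is the silhouette argmax among those candidates.
    """
    n = len(profiles)
    if n < 4:
        raise ValueError("need at least 4 profiles for model selection")
    k_range = k_range or range(1, 21)
    ks = [k for k in k_range if 1 <= k <= n - 1]
    if not ks:
        raise ValueError("empty usable k range")
    ids = [p.votu_id for p in profiles]
    X = np.vstack([p.values for p in profiles])
    dist = squareform(pdist(X))
    dist_sq = dist ** 2

    pam_parts: dict[int, tuple[list[int], np.ndarray]] = {}
    sse_pam: dict[int, float] = {}
    for k in ks:
        meds, assign = _pam(dist, k)
        pam_parts[k] = (meds, assign)
        sse_pam[k] = _within_sse(dist_sq, meds, assign)

    Z = linkage(X, method="ward")
    sse_ward: dict[int, float] = {}
    for k in ks:
        labels = fcluster(Z, t=k, criterion="maxclust") - 1
        sse = 0.0
        for c in np.unique(labels):
            sub = X[labels == c]
            sse += ((sub - sub.mean(axis=0)) ** 2).sum()
        sse_ward[k] = float(sse)

    sil: dict[int, float] = {}
    for k in ks:
        if k < 2 or k >= n:
            sil[k] = float("nan")
            continue
        labels = pam_parts[k][1]
        if len(np.unique(labels)) < 2:
            sil[k] = float("nan")
            continue
        sil[k] = float(silhouette_score(dist, labels, metric="precomputed"))

    # elbow: the point of the PAM SSE curve furthest below its end-to-end
    # chord (the standard knee criterion), cross-checked against Ward
    elbow = _knee(sse_pam)
    elbow_ward = _knee(sse_ward)
    if elbow_ward != elbow:
        logger.info("select_k: PAM elbow %d vs Ward elbow %d", elbow, elbow_ward)
    candidates = tuple(k for k in (elbow, elbow + 1) if k in sse_pam)
    scored = [k for k in candidates if not np.isnan(sil.get(k, float("nan")))]
    chosen = max(scored, key=lambda k: sil[k]) if scored else elbow

    meds, assign = pam_parts[chosen]
    logger.info("select_k: elbow=%d candidates=%s chosen=%d", elbow, candidates, chosen)
    return ClusterModel(
        k=chosen, medoids=[ids[m] for m in meds],
        assignment={i: int(c) for i, c in zip(ids, assign)},
        sse_by_k={"pam": sse_pam, "ward": sse_ward},
        silhouette_by_k=sil, chosen_k=chosen, seed=seed,
        candidate_ks=candidates)


# ---------------------------------------------------------------------------
# cluster profiling
# ---------------------------------------------------------------------------

def _zscore_across(df: pd.DataFrame) -> pd.DataFrame:
    """Z-score each column across the rows (clusters); constant columns -> 0."""
    mu = df.mean(axis=0)
    sd = df.std(axis=0, ddof=0)
    out = (df - mu) / sd.replace(0, np.nan)
    return out.fillna(0.0)


def profile_clusters(model: ClusterModel, profiles: list[ZProfile],
                     abundance: pd.DataFrame, votu_taxonomy: pd.DataFrame,
                     amg: pd.DataFrame | None = None) -> list[ClusterProfile]:
    """Mean Z trajectory plus family and AMG pathway Z-profiles per cluster.

    Family (resp. pathway) totals sum member-vOTU relative abundance per
    viral family (resp. AMG KEGG pathway) within each cluster and are
    Z-scored *across clusters*; families or pathways absent from a cluster
    are flagged.  ``amg`` must carry a ``votu_id`` column (AMG annotations
    already mapped to vOTUs).
    """
    prof_by_id = {p.votu_id: p for p in profiles}
    members: dict[int, list[str]] = {}
    for vid, c in model.assignment.items():
        members.setdefault(c, []).append(vid)
    clusters = sorted(members)

    fam_of = votu_taxonomy.set_index("votu_id")["family"].to_dict()
    votu_total = abundance.sum(axis=1)

    fam_totals = pd.DataFrame(0.0, index=clusters,
                              columns=sorted(set(fam_of.values())))
    for c in clusters:
        for vid in members[c]:
            fam = fam_of.get(vid)
            if fam is not None and vid in votu_total.index:
                fam_totals.loc[c, fam] += votu_total[vid]
    fam_z = _zscore_across(fam_totals)

    if amg is not None and not amg.empty:
        pathways = sorted(amg["kegg_pathway"].unique())
        amg_by_votu = amg.groupby("votu_id")["kegg_pathway"].value_counts()
        path_totals = pd.DataFrame(0.0, index=clusters, columns=pathways)
        for (vid, path), cnt in amg_by_votu.items():
            c = model.assignment.get(vid)
            if c is not None and vid in votu_total.index:
                path_totals.loc[c, path] += cnt * votu_total[vid]
        path_z = _zscore_across(path_totals)
    else:
        path_totals = pd.DataFrame(index=clusters)
        path_z = path_totals.copy()

    out = []
    for c in clusters:
        traj = np.mean([prof_by_id[v].values for v in members[c] if v in prof_by_id],
                       axis=0)
        out.append(ClusterProfile(
            cluster=c,
            mean_trajectory=pd.Series(traj, index=abundance.columns),
            family_z=fam_z.loc[c],
            pathway_z=path_z.loc[c] if not path_z.empty else pd.Series(dtype=float),
            absent_families=tuple(fam_totals.columns[fam_totals.loc[c] == 0]),
            absent_pathways=tuple(path_totals.columns[path_totals.loc[c] == 0])
            if not path_totals.empty else (),
        ))
    return out
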
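"""Community ecology statistics implemented from their defining formulas.

Diversity indices, the centred log-ratio (CLR) transform, non-metric
multidimensional scaling (NMDS) by isotonic regression + majorization,
ANOSIM and PERMANOVA permutation tests, single-variable ordination fitting
(envfit), exhaustive best-environmental-subset search (bioenv), the exact
paired Wilcoxon signed-rank test, and the per-site abiotic summary table.

Conventions: natural logarithms throughout (Shannon entropy in nats);
permutation p-values use the add-one rule so p is never reported as zero;
every stochastic routine takes an explicit seed.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata, spearmanr
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger("halovir")

#: abiotic columns summarised per site
ABIOTIC_COLUMNS = ("temp_C", "do_mg_per_L", "salinity_ppt", "pH",
                   "nh4_uM", "no3_uM", "no2_uM", "autofluor_cells_per_mL")


# ---------------------------------------------------------------------------
# diversity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversityResult:
    shannon: float          # nats
    pielou: float           # H / ln S, NaN when S <= 1
    chao1: float            # NaN for non-integer input
    richness: int


def diversity(abundances) -> DiversityResult:
    """Shannon (nats), Pielou evenness, Chao1 and observed richness.

    Chao1 = S + F1 (F1 - 1) / (2 (F2 + 1)) with F1/F2 the singleton and
    doubleton counts; it is only defined for integer counts and reported as
    NaN otherwise.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero abundance vector")
    nz = x[x > 0]
    p = nz / total
    shannon = float(-(p * np.log(p)).sum())
    richness = int(len(nz))
    pielou = shannon / math.log(richness) if richness > 1 else float("nan")
    integral = np.allclose(x, np.round(x))
    if integral:
        f1 = int((np.round(nz) == 1).sum())
        f2 = int((np.round(nz) == 2).sum())
        chao1 = richness + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    else:
        chao1 = float("nan")
    return DiversityResult(shannon, pielou, chao1, richness)


# ---------------------------------------------------------------------------
# compositional transform and distances
# ---------------------------------------------------------------------------

def clr(matrix: pd.DataFrame | np.ndarray, pseudocount: float | None = None) -> pd.DataFrame:
    """Centred log-ratio transform, one composition per row.

    ``pseudocount`` defaults to half the smallest nonzero value of the
    matrix when zeros are present (standard compositional practice), else
    zero.  Each output row sums to zero; positive rows are invariant to
    rescaling when no pseudocount is needed.
    """
    df = pd.DataFrame(matrix).astype(float)
    x = df.values
    if (x < 0).any():
        raise ValueError("CLR input must be non-negative")
    if pseudocount is None:
        nz = x[x > 0]
        pseudocount = nz.min() / 2.0 if (x == 0).any() and len(nz) else 0.0
    logged = np.log(x + pseudocount)
    out = logged - logged.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def community_distances(values: pd.DataFrame, method: str = "clr_euclidean",
                        pseudocount: float | None = None) -> pd.DataFrame:
    """Sample-by-sample distances from a vOTU x sample abundance table."""
    samples = values.columns
    comp = values.T  # samples as rows
    if method == "clr_euclidean":
        d = pdist(clr(comp, pseudocount).values, metric="euclidean")
    elif method == "braycurtis":
        d = pdist(comp.values, metric="braycurtis")
    else:
        raise ValueError(f"unknown distance method {method!r}")
    return pd.DataFrame(squareform(d), index=samples, columns=samples)


def _check_distance(dist: pd.DataFrame | np.ndarray) -> np.ndarray:
    d = np.asarray(pd.DataFrame(dist).values, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class Ordination:
    coordinates: pd.DataFrame   # sample x dims
    stress: float               # Kruskal stress-1
    n_restarts: int
    seed: int


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = (d ** 2).sum()
    if denom == 0:
        return 0.0
    return math.sqrt(((d - dhat) ** 2).sum() / denom)


def nmds(dist: pd.DataFrame | np.ndarray, dims: int = 2, restarts: int = 20,
         seed: int = 0, max_iter: int = 300, tol: float = 1e-7) -> Ordination:
    """Non-metric MDS minimising Kruskal stress-1.

    Each restart starts from classical metric scaling (plus seeded jitter
    after the first) and alternates isotonic regression of the embedding
    distances on the input dissimilarity order with a Guttman-transform
    majorization step; iteration stops as soon as stress fails to decrease,
    so the per-restart stress trace is non-increasing.  The best restart is
    returned.
    """
    D = _check_distance(dist)
    n = D.shape[0]
    labels = (dist.index if isinstance(dist, pd.DataFrame)
              else pd.RangeIndex(n))
    dcond = squareform(D, checks=False)
    order = np.argsort(dcond, kind="stable")

    # classical scaling start
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, V = np.linalg.eigh(B)
    idx = np.argsort(w)[::-1][:dims]
    X0 = V[:, idx] * np.sqrt(np.clip(w[idx], 0, None))

    rng = np.random.default_rng(seed)
    scale = max(np.abs(X0).max(), 1e-6)
    best_X, best_stress = None, math.inf
    iso = IsotonicRegression(increasing=True)
    for r in range(max(restarts, 1)):
        X = X0.copy() if r == 0 else X0 + rng.normal(0, 0.1 * scale, X0.shape)
        prev = math.inf
        for _ in range(max_iter):
            d = pdist(X)
            dhat = np.empty_like(d)
            dhat[order] = iso.fit_transform(np.arange(len(d)), d[order])
            s = _stress1(d, dhat)
            if s > prev - tol:
                break
            prev = s
            # Guttman transform with disparities dhat
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            Bmat = -squareform(ratio, checks=False)
            np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
            X = Bmat @ X / n
        if prev < best_stress:
            best_stress, best_X = prev, X
    if best_stress is math.inf:  # degenerate: all distances zero
        best_stress, best_X = 0.0, X0
    coords = pd.DataFrame(best_X, index=labels,
                          columns=[f"NMDS{i + 1}" for i in range(dims)])
    return Ordination(coords, float(best_stress), max(restarts, 1), seed)


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    seed: int
    exhaustive: bool = False


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_permutations: int
    seed: int


def _grouping_array(grouping, n: int) -> np.ndarray:
    g = np.asarray(pd.Series(grouping).values)
    if len(g) != n:
        raise ValueError("grouping length must match the distance matrix")
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two members")
    return g


def _n_label_orderings(g: np.ndarray) -> float:
    _, counts = np.unique(g, return_counts=True)
    return math.factorial(len(g)) / math.prod(math.factorial(int(c)) for c in counts)


def _anosim_R(rank_sq: np.ndarray, g: np.ndarray) -> float:
    n = len(g)
    within = g[:, None] == g[None, :]
    iu = np.triu_indices(n, 1)
    wmask = within[iu]
    r = rank_sq[iu]
    r_within = r[wmask].mean()
    r_between = r[~wmask].mean()
    return (r_between - r_within) / (n * (n - 1) / 4.0)


def anosim(dist, grouping, n_permutations: int = 9_999, seed: int = 0,
           exhaustive_limit: int = 10_000) -> AnosimResult:
    """Rank-based analysis of similarities.

    R contrasts mean between- vs within-group ranks of the pairwise
    distances, scaled by n(n-1)/4 so R = 1 when every between-group rank
    exceeds every within-group rank.  When the number of distinct label
    orderings is at most ``exhaustive_limit`` the null is enumerated
    completely (p = fraction of orderings with R at least the observed,
    observed included); otherwise ``n_permutations`` seeded shuffles with
    the add-one rule.  R depends on the distances only through their ranks.
    """
    D = _check_distance(dist)
    n = D.shape[0]
    g = _grouping_array(grouping, n)
    iu = np.triu_indices(n, 1)
    rank_sq = np.zeros_like(D)
    rank_sq[iu] = rankdata(D[iu])
    rank_sq = rank_sq + rank_sq.T

    R_obs = _anosim_R(rank_sq, g)
    if _n_label_orderings(g) <= exhaustive_limit:
        hits = total = 0
        for perm in _distinct_orderings(g):
            total += 1
            if _anosim_R(rank_sq, perm) >= R_obs - 1e-12:
                hits += 1
        return AnosimResult(R_obs, hits / total, total, seed, exhaustive=True)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if _anosim_R(rank_sq, rng.permutation(g)) >= R_obs - 1e-12:
            hits += 1
    return AnosimResult(R_obs, (1 + hits) / (1 + n_permutations),
                        n_permutations, seed)


def _distinct_orderings(g: np.ndarray):
    """All distinct orderings of a label multiset (lexicographic)."""
    labels = sorted(g.tolist())

    def rec(prefix, remaining):
        if not remaining:
            yield np.asarray(prefix, dtype=object)
            return
        seen = set()
        for i, lab in enumerate(remaining):
            if lab in seen:
                continue
            seen.add(lab)
            yield from rec(prefix + [lab], remaining[:i] + remaining[i + 1:])

    yield from rec([], labels)


def _permanova_stats(d2: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    n = len(g)
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    labels, counts = np.unique(g, return_counts=True)
    for lab, cnt in zip(labels, counts):
        mask = g == lab
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(int(cnt), 1)].sum() / cnt
    ss_between = ss_total - ss_within
    a = len(labels)
    f = (ss_between / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else math.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(dist, grouping, n_permutations: int = 9_999, seed: int = 0) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    Sums of squares follow the Gower decomposition of squared distances;
    pseudo-F = (SS_between / df_b) / (SS_within / df_w); the p-value
    permutes group labels with the add-one rule.
    """
    D = _check_distance(dist)
    g = _grouping_array(grouping, D.shape[0])
    d2 = D ** 2
    f_obs, r2 = _permanova_stats(d2, g)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        f_p, _ = _permanova_stats(d2, rng.permutation(g))
        if f_p >= f_obs - 1e-12:
            hits += 1
    return PermanovaResult(f_obs, r2, (1 + hits) / (1 + n_permutations),
                           n_permutations, seed)


# ---------------------------------------------------------------------------
# envfit and bioenv
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EnvFitResult:
    variable: str
    r2: float
    p: float


def envfit(ordination: Ordination, values, name: str = "env",
           n_permutations: int = 999, seed: int = 0) -> EnvFitResult:
    """Squared multiple correlation of one variable with the ordination.

    r2 is the R-squared of the variable regressed on the ordination axes;
    the p-value permutes the variable.  A constant variable gives r2 = 0
    with a warning.
    """
    X = ordination.coordinates.values
    y = np.asarray(values, dtype=float)
    if len(y) != X.shape[0]:
        raise ValueError("variable length must match the ordination")
    if np.isnan(y).any():
        raise ValueError("missing values not allowed")
    if np.allclose(y, y[0]):
        logger.warning("envfit: variable %r is constant; r2 = 0", name)
        return EnvFitResult(name, 0.0, 1.0)

    Xc = np.column_stack([np.ones(len(y)), X])

    def r2_of(v: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(Xc, v, rcond=None)
        resid = v - Xc @ beta
        sst = ((v - v.mean()) ** 2).sum()
        return float(1 - resid @ resid / sst) if sst > 0 else 0.0

    obs = r2_of(y)
    rng = np.random.default_rng(seed)
    hits = sum(r2_of(rng.permutation(y)) >= obs - 1e-12
               for _ in range(n_permutations))
    return EnvFitResult(name, obs, (1 + hits) / (1 + n_permutations))


@dataclass
class BioenvResult:
    best_subset: tuple[str, ...]
    rho: float
    table: pd.DataFrame   # every subset with its Spearman rho


def bioenv(community_dist, env: pd.DataFrame,
           max_subset_size: int | None = None) -> BioenvResult:
    """Exhaustive best-subset search over standardized abiotic variables.

    Every non-empty variable subset up to ``max_subset_size`` is scored by
    the Spearman rank correlation between Euclidean distances on the
    z-scored subset and the community distances (upper triangles).  With
    more than 20 variables an explicit ``max_subset_size`` is required.
    """
    D = _check_distance(community_dist)
    cols = list(env.columns)
    if env.isna().any().any():
        raise ValueError("missing values not allowed in the env table")
    if len(cols) > 20 and max_subset_size is None:
        raise ValueError("more than 20 variables: set max_subset_size explicitly")
    max_subset_size = max_subset_size or len(cols)
    Z = (env - env.mean()) / env.std(ddof=1)
    Z = Z.fillna(0.0)  # constant columns carry no distance information
    iu = np.triu_indices(D.shape[0], 1)
    comm = D[iu]
    rows = []
    best = (-math.inf, ())
    for size in range(1, max_subset_size + 1):
        for subset in itertools.combinations(cols, size):
            ed = pdist(Z[list(subset)].values)
            rho = spearmanr(comm, ed).statistic
            rho = 0.0 if np.isnan(rho) else float(rho)
            rows.append({"subset": subset, "size": size, "rho": rho})
            if rho > best[0]:
                best = (rho, subset)
    table = pd.DataFrame(rows)
    return BioenvResult(best[1], best[0], table)


# ---------------------------------------------------------------------------
# paired Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Exact two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; ties get mid-ranks.  For n <= 25 the
    two-sided p enumerates the complete sign-assignment null (by dynamic
    programming over doubled ranks, identical to summing over all 2^n sign
    vectors); larger n uses the tie-corrected normal approximation.
    Returns ``(W_plus, p)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 nonzero differences")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        # DP over doubled mid-ranks (integers); counts subsets by rank sum
        r2 = np.round(2 * ranks).astype(int)
        total = int(r2.sum())
        dist = np.zeros(total + 1, dtype=float)
        dist[0] = 1.0
        for r in r2:
            dist[r:] = dist[r:] + dist[:-r or None]
        dist /= 2.0 ** n
        w2 = int(round(2 * w_plus))
        p_le = dist[: w2 + 1].sum()
        p_ge = dist[w2:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 \
            - (tie_counts ** 3 - tie_counts).sum() / 48.0
        from scipy.stats import norm
        z = (w_plus - mean) / math.sqrt(var)
        p = float(2 * norm.sf(abs(z)))
    return w_plus, p


# ---------------------------------------------------------------------------
# site summary
# ---------------------------------------------------------------------------

def site_summary(metadata: pd.DataFrame, sites: tuple[str, str] = ("LOC", "RB"),
                 columns=ABIOTIC_COLUMNS) -> pd.DataFrame:
    """Per-variable site means, differences, ratios and paired Wilcoxon p.

    One row per abiotic column with each site's mean over its sampling
    dates, the first-minus-second difference, both mean ratios, and the
    exact paired Wilcoxon p over dates sampled at both sites (unpaired
    dates are dropped with a warning).
    """
    s1, s2 = sites
    m1 = metadata[metadata["site"] == s1].set_index("date")
    m2 = metadata[metadata["site"] == s2].set_index("date")
    if m1.empty or m2.empty:
        raise ValueError(f"metadata must contain both sites {sites}")
    shared = m1.index.intersection(m2.index)
    if len(shared) < len(m1) or len(shared) < len(m2):
        logger.warning("site_summary: restricting the paired test to %d shared dates",
                       len(shared))
    rows = []
    for col in columns:
        x1 = m1[col].astype(float)
        x2 = m2[col].astype(float)
        mean1, mean2 = x1.mean(), x2.mean()
        try:
            _, p = wilcoxon_signed_rank(x1.loc[shared].values, x2.loc[shared].values)
        except ValueError:
            p = float("nan")
        rows.append({
            "variable": col, f"mean_{s1}": mean1, f"mean_{s2}": mean2,
            "difference": mean1 - mean2,
            f"ratio_{s1}_over_{s2}": mean1 / mean2 if mean2 else float("inf"),
            f"ratio_{s2}_over_{s1}": mean2 / mean1 if mean1 else float("inf"),
            "wilcoxon_p": p,
        })
    return pd.DataFrame(rows).set_index("variable")
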
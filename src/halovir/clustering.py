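"""vOTU dereplication: ANI/AF estimation and greedy centroid clustering.

Viral contigs are clustered into viral operational taxonomic units (vOTUs)
whenever their average nucleotide identity (ANI) is at least 0.95 over an
aligned fraction (AF) of at least 0.85 of the *shorter* sequence — the
standard viral dereplication convention.

ANI is estimated from k-mer-seeded alignment blocks: exact shared k-mers on
either strand are chained along near-constant diagonals, each chained block
is globally aligned with edlib, and identity is counted over aligned
(non-gap) columns.  A brute-force dynamic-programming oracle
(:func:`ani_oracle_dp`, best local alignment of the full sequences) is kept
in the package for cross-checks on short sequences; it shares no code with
the seeded path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib
import pandas as pd
from Bio import Align
from Bio.Seq import reverse_complement

from halovir.io import parse_contig_id

logger = logging.getLogger("halovir")

KMER = 15            # seed length
MIN_BLOCK = 100      # minimum chained-block span (bp) kept for alignment
CHAIN_GAP = 500      # max gap (bp) between seeds chained into one block
DIAG_BAND = 30       # diagonal tolerance when banding seeds (absorbs indels)


@dataclass(frozen=True)
class AniResult:
    """Identity over aligned columns (gap-excluded) and aligned fraction
    of the shorter sequence."""

    ani: float
    aligned_fraction: float


@dataclass
class VOtu:
    """One cluster of viral contigs; the longest member is representative."""

    votu_id: str
    representative: str
    members: set[str] = field(default_factory=set)

    def metagenome_membership(self, delimiter: str = "||") -> set[str]:
        return {parse_contig_id(m, delimiter)[0] for m in self.members}

    def site_membership(self, delimiter: str = "||") -> set[str]:
        return {parse_contig_id(m, delimiter)[1] for m in self.members}


# ---------------------------------------------------------------------------
# seeded ANI
# ---------------------------------------------------------------------------

def _kmers(seq: str, k: int = KMER) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i:i + k], []).append(i)
    return index


class TargetIndex:
    """Both-strand k-mer index of one sequence, reusable across queries."""

    def __init__(self, seq: str, k: int = KMER):
        if not seq:
            raise ValueError("empty sequence")
        self.seq = seq
        self.k = k
        self.rc = reverse_complement(seq)
        self.strands = ((seq, _kmers(seq, k)), (self.rc, _kmers(self.rc, k)))


def _seed_matches(query: str, index: dict[str, list[int]], k: int
                  ) -> list[tuple[int, int]]:
    out = []
    for i in range(len(query) - k + 1):
        hits = index.get(query[i:i + k])
        if hits:
            out.extend((i, j) for j in hits)
    return out


def _chain_blocks(matches: list[tuple[int, int]], k: int
                  ) -> list[tuple[int, int, int, int]]:
    """Band seeds by diagonal and chain them into (qs, qe, ts, te) blocks."""
    if not matches:
        return []
    matches = sorted(matches, key=lambda m: (m[0] - m[1], m[0]))
    groups: list[list[tuple[int, int]]] = [[matches[0]]]
    for m in matches[1:]:
        prev = groups[-1][-1]
        same_band = abs((m[0] - m[1]) - (prev[0] - prev[1])) <= DIAG_BAND
        if same_band and 0 <= m[0] - prev[0] <= CHAIN_GAP:
            groups[-1].append(m)
        else:
            groups.append([m])
    spans = []
    for blk in groups:
        qs, qe = min(q for q, _ in blk), max(q for q, _ in blk) + k
        ts, te = min(t for _, t in blk), max(t for _, t in blk) + k
        if qe - qs >= MIN_BLOCK and te - ts >= MIN_BLOCK:
            spans.append((qs, qe, ts, te))
    # merge blocks overlapping on the query axis so no column counts twice
    spans.sort()
    merged: list[list[int]] = []
    for qs, qe, ts, te in spans:
        if merged and qs < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], qe)
            merged[-1][2] = min(merged[-1][2], ts)
            merged[-1][3] = max(merged[-1][3], te)
        else:
            merged.append([qs, qe, ts, te])
    return [tuple(m) for m in merged]


def _cigar_counts(cigar: str) -> tuple[int, int, int]:
    """(matches, mismatches, gap columns) from an edlib extended CIGAR."""
    eq = mm = gap = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n, num = int(num), ""
        if ch == "=":
            eq += n
        elif ch == "X":
            mm += n
        else:  # I / D
            gap += n
    return eq, mm, gap


def pairwise_ani(seq_a: str, seq_b: str | TargetIndex) -> AniResult:
    """Seeded ANI/AF between two sequences, considering both strands.

    Identical sequences score ``(1.0, 1.0)``; sequences sharing no chained
    seed block score ``(0.0, 0.0)``.  ``seq_b`` may be a prebuilt
    :class:`TargetIndex` to amortise indexing during clustering.
    """
    target = seq_b if isinstance(seq_b, TargetIndex) else TargetIndex(seq_b)
    if not seq_a:
        raise ValueError("empty sequence")
    best_eq = best_mm = 0
    best_spans: list[tuple[int, int]] = []
    for text, index in target.strands:
        eq_total = mm_total = 0
        qspans = []
        for qs, qe, ts, te in _chain_blocks(_seed_matches(seq_a, index, target.k), target.k):
            res = edlib.align(seq_a[qs:qe], text[ts:te], task="path", mode="NW")
            eq, mm, _ = _cigar_counts(res["cigar"])
            eq_total += eq
            mm_total += mm
            qspans.append((qs, qe))
        if eq_total + mm_total > best_eq + best_mm:
            best_eq, best_mm, best_spans = eq_total, mm_total, qspans
    if best_eq + best_mm == 0:
        return AniResult(0.0, 0.0)
    shorter = min(len(seq_a), len(target.seq))
    covered = 0
    end = -1
    for s, e in sorted(best_spans):
        s = max(s, end)
        if e > s:
            covered += e - s
            end = e
    return AniResult(best_eq / (best_eq + best_mm), min(covered, shorter) / shorter)


# ---------------------------------------------------------------------------
# brute-force DP oracle
# ---------------------------------------------------------------------------

def ani_oracle_dp(seq_a: str, seq_b: str) -> AniResult:
    """Full dynamic-programming (best local alignment) ANI/AF.

    Smith-Waterman over the complete sequences on both strands; identity is
    counted over aligned non-gap columns of the best-scoring alignment, and
    the aligned fraction over the columns the alignment consumes on the
    shorter sequence.  Quadratic — intended for sequences up to a few kb.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner(mode="local", match_score=1.0,
                                    mismatch_score=-2.0, open_gap_score=-4.0,
                                    extend_gap_score=-2.0)
    best = None
    for target in (seq_b, reverse_complement(seq_b)):
        aln = aligner.align(seq_a, target)
        if len(aln) == 0:
            continue
        top = aln[0]
        if best is None or top.score > best.score:
            best = top
    if best is None or best.score <= 0:
        return AniResult(0.0, 0.0)
    counts = best.counts()
    eq, mm = counts.identities, counts.mismatches
    if eq + mm == 0:
        return AniResult(0.0, 0.0)
    a_blocks, b_blocks = best.aligned
    span_a = int(sum(e - s for s, e in a_blocks))
    span_b = int(sum(e - s for s, e in b_blocks))
    shorter_span = span_a if len(seq_a) <= len(seq_b) else span_b
    af = min(shorter_span, min(len(seq_a), len(seq_b))) / min(len(seq_a), len(seq_b))
    return AniResult(eq / (eq + mm), af)


# ---------------------------------------------------------------------------
# greedy centroid clustering
# ---------------------------------------------------------------------------

def cluster_votus(sequences: dict[str, str], ani_min: float = 0.95,
                  af_min: float = 0.85, delimiter: str = "||") -> list[VOtu]:
    """Greedy centroid clustering of viral contigs into vOTUs.

    Contigs are processed longest-first (ties by id); each joins the
    existing representative with the highest qualifying ANI (AF and ANI
    thresholds on the shorter sequence; ties go to the earlier-founded
    vOTU), else founds a new vOTU.  Deterministic given the input set.
    """
    order = sorted(sequences, key=lambda c: (-len(sequences[c]), c))
    votus: list[VOtu] = []
    rep_indexes: list[TargetIndex] = []
    for cid in order:
        seq = sequences[cid]
        best_i, best_ani = None, -1.0
        for i, idx in enumerate(rep_indexes):
            r = pairwise_ani(seq, idx)
            if r.ani >= ani_min and r.aligned_fraction >= af_min and r.ani > best_ani:
                best_i, best_ani = i, r.ani
        if best_i is None:
            votus.append(VOtu(votu_id=f"votu{len(votus):05d}",
                              representative=cid, members={cid}))
            rep_indexes.append(TargetIndex(seq))
        else:
            votus[best_i].members.add(cid)
    logger.info("clustering: %d contigs -> %d vOTUs", len(sequences), len(votus))
    return votus


def cluster_votus_oracle(sequences: dict[str, str], ani_min: float = 0.95,
                         af_min: float = 0.85) -> list[set[str]]:
    """All-pairs oracle clustering (single-linkage components) for small sets.

    Computes every pairwise ANI with the DP oracle and returns the connected
    components of the >= threshold graph — an independent reference for the
    greedy clustering on fixtures where clusters are well separated.
    """
    ids = sorted(sequences)
    parent = {c: c for c in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            r = ani_oracle_dp(sequences[a], sequences[b])
            if r.ani >= ani_min and r.aligned_fraction >= af_min:
                parent[find(a)] = find(b)
    comps: dict[str, set[str]] = {}
    for c in ids:
        comps.setdefault(find(c), set()).add(c)
    return sorted(comps.values(), key=lambda s: sorted(s)[0])


# ---------------------------------------------------------------------------
# membership summary
# ---------------------------------------------------------------------------

def summarize_membership(votus: list[VOtu], sites: tuple[str, str] = ("LOC", "RB"),
                         delimiter: str = "||") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-vOTU membership plus the cross-site aggregate.

    Returns ``(per_votu, aggregate)``: the first has one row per vOTU with
    its metagenome count and site class (``<site>-only`` or ``both``); the
    second, per metagenome count, the number of vOTUs and the fraction found
    at both sites, plus total counts per site class.
    """
    rows = []
    for v in votus:
        vsites = v.site_membership(delimiter)
        cls = "both" if len(vsites) > 1 else f"{next(iter(vsites))}-only"
        rows.append({"votu_id": v.votu_id, "representative": v.representative,
                     "n_members": len(v.members),
                     "n_metagenomes": len(v.metagenome_membership(delimiter)),
                     "site_class": cls})
    per_votu = pd.DataFrame(rows)
    if per_votu.empty:
        return per_votu, pd.DataFrame(columns=["n_metagenomes", "n_votus", "fraction_both_sites"])
    agg = (per_votu.groupby("n_metagenomes")
           .agg(n_votus=("votu_id", "size"),
                fraction_both_sites=("site_class", lambda s: (s == "both").mean()))
           .reset_index())
    return per_votu, agg


def site_class_counts(per_votu: pd.DataFrame) -> pd.Series:
    """Total vOTU counts per site class (single-site vs both)."""
    if per_votu.empty:
        return pd.Series(dtype=int)
    return per_votu["site_class"].value_counts().sort_index()
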
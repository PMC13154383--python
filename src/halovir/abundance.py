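"""Detection-filtered, length- and depth-normalised vOTU abundance.

A vOTU is *detected* in a sample only when the coverage breadth of its
representative contig exceeds 0.75 (strictly) — the standard viromics
guard against spurious recruitment.  Detected read counts are converted to
relative abundance as reads per kbp of representative per million sample
reads.  An unfiltered count matrix (sub-threshold counts included) is kept
alongside for the temporal-dynamics pipeline, which deliberately uses all
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from halovir.clustering import VOtu
from halovir.io import strip_trim_suffix

logger = logging.getLogger("halovir")


class IntervalError(ValueError):
    """A coverage interval extends outside its contig."""


@dataclass
class AbundanceMatrix:
    """vOTU x sample relative abundance with its detection mask.

    ``values`` is zero wherever ``detected`` is False; ``counts`` holds the
    parallel unfiltered vOTU read counts.
    """

    values: pd.DataFrame        # relative abundance (reads/kbp/Mreads)
    detected: pd.DataFrame      # boolean, same shape
    counts: pd.DataFrame        # unfiltered integer counts, same shape
    sample_depths: pd.Series    # total reads per sample
    lengths: pd.Series          # representative length per vOTU

    def __post_init__(self) -> None:
        assert self.values.shape == self.detected.shape == self.counts.shape
        assert (self.values.values >= 0).all()
        assert (self.values.values[~self.detected.values] == 0).all()


def coverage_breadth(intervals: list[tuple[int, int]], contig_length_bp: int) -> float:
    """Fraction of the contig covered by the union of 0-based half-open intervals."""
    if contig_length_bp <= 0:
        raise IntervalError("contig length must be positive")
    covered = 0
    end = -1
    for s, e in sorted(intervals):
        if s < 0 or e > contig_length_bp:
            raise IntervalError(
                f"interval [{s}, {e}) outside contig of length {contig_length_bp}")
        s = max(s, end)
        if e > s:
            covered += e - s
            end = e
    return covered / contig_length_bp


def detect(breadth: float, threshold: float = 0.75) -> bool:
    """Strict breadth criterion: detected iff breadth > threshold."""
    if not 0.0 <= breadth <= 1.0:
        raise ValueError(f"breadth {breadth} outside [0, 1]")
    return breadth > threshold


def normalize(read_count: float, length_bp: int, sample_total_reads: int) -> float:
    """Reads per kbp of sequence per million sample reads."""
    if length_bp <= 0 or sample_total_reads <= 0:
        raise ValueError("length and sample depth must be positive")
    return read_count / (length_bp / 1000.0) / (sample_total_reads / 1e6)


def build_matrix(counts: pd.DataFrame, coverage: pd.DataFrame,
                 sample_depths: pd.DataFrame, votus: list[VOtu],
                 contig_lengths: dict[str, int],
                 breadth_threshold: float = 0.75,
                 delimiter: str = "||") -> AbundanceMatrix:
    """Aggregate per-contig read counts into the vOTU x sample matrices.

    vOTU counts sum the reads of all member contigs (a trimmed consensus
    variant inherits the counts of its base contig); breadth is evaluated on
    the representative.  Cells failing the strict breadth criterion are
    zeroed in the filtered matrix but kept in the unfiltered count matrix.
    """
    samples = list(sample_depths["sample_id"])
    depth = sample_depths.set_index("sample_id")["total_reads"]
    missing = set(counts["sample_id"]) - set(samples)
    if missing:
        raise ValueError(f"samples in counts but absent from metadata: {sorted(missing)}")

    base_of = {}  # read-count contig id -> votu id (via member base names)
    rep_base = {}
    lengths = {}
    for v in votus:
        for m in v.members:
            base_of[strip_trim_suffix(m, delimiter)] = v.votu_id
        rep_base[v.votu_id] = strip_trim_suffix(v.representative, delimiter)
        lengths[v.votu_id] = contig_lengths[rep_base[v.votu_id]]

    votu_ids = [v.votu_id for v in votus]
    cmat = pd.DataFrame(0, index=votu_ids, columns=samples, dtype=np.int64)
    ctab = counts.copy()
    ctab["votu_id"] = ctab["contig_id"].map(
        lambda c: base_of.get(strip_trim_suffix(c, delimiter)))
    ctab = ctab.dropna(subset=["votu_id"])
    grouped = ctab.groupby(["votu_id", "sample_id"])["reads"].sum()
    for (v, s), r in grouped.items():
        cmat.loc[v, s] = r

    # representative breadth per (votu, sample)
    cov = coverage.copy()
    cov["base"] = cov["contig_id"].map(lambda c: strip_trim_suffix(c, delimiter))
    det = pd.DataFrame(False, index=votu_ids, columns=samples)
    by_key = cov.groupby(["base", "sample_id"])
    for v in votu_ids:
        rb = rep_base[v]
        L = lengths[v]
        for s in samples:
            try:
                sub = by_key.get_group((rb, s))
            except KeyError:
                continue
            b = coverage_breadth(list(zip(sub["start"], sub["end"])), L)
            det.loc[v, s] = detect(b, breadth_threshold)

    values = pd.DataFrame(0.0, index=votu_ids, columns=samples)
    for v in votu_ids:
        for s in samples:
            if det.loc[v, s]:
                values.loc[v, s] = normalize(cmat.loc[v, s], lengths[v], int(depth[s]))
    n_det = det.sum(axis=0)
    for s in samples:
        logger.info("abundance: %s detected %d vOTUs", s, int(n_det[s]))
    return AbundanceMatrix(values=values, detected=det, counts=cmat,
                           sample_depths=depth, lengths=pd.Series(lengths))
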
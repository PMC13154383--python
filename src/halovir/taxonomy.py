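"""Gene-majority taxonomy and source-environment assignment for vOTUs.

A rank label is assigned when *strictly more than half* of the annotated
genes agree on it, walking ranks from realm down to family; the first rank
without a strict majority, and all ranks below it, become
``"Unknown <deepest assigned ancestor>"``.  The source environment uses the
same strict-majority vote over environment-labelled genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger("halovir")

RANKS = ("realm", "kingdom", "phylum", "class", "order", "family")

ENVIRONMENT_VOCABULARY = ("marine", "freshwater", "non-marine saline/alkaline", "unknown")


@dataclass(frozen=True)
class Lineage:
    """Ranked labels realm..family; unresolved ranks are Unknown-qualified."""

    realm: str
    kingdom: str
    phylum: str
    klass: str
    order: str
    family: str

    def as_tuple(self) -> tuple[str, ...]:
        return (self.realm, self.kingdom, self.phylum, self.klass,
                self.order, self.family)

    @property
    def deepest_assigned(self) -> str:
        """The most specific non-Unknown label, or 'Unknown'."""
        last = "Unknown"
        for label in self.as_tuple():
            if label.startswith("Unknown"):
                break
            last = label
        return last


def _unknown_below(assigned: list[str]) -> Lineage:
    anchor = assigned[-1] if assigned else ""
    unknown = f"Unknown {anchor}".strip()
    labels = assigned + [unknown] * (len(RANKS) - len(assigned))
    return Lineage(*labels)


def assign_taxonomy(gene_hits: pd.DataFrame, majority: float = 0.5) -> Lineage:
    """Majority-rule lineage from one vOTU's annotated gene hits.

    ``gene_hits`` needs the rank columns of the gene-taxonomy schema; empty
    strings mean no annotation at that rank.  The denominator at each rank
    is the number of genes annotated at *any* rank (unannotated genes never
    dilute the vote); zero annotated genes yield a fully Unknown lineage.
    Output is independent of gene order, and adding genes that agree with
    the current majority can only deepen the assignment.
    """
    if gene_hits.empty:
        return _unknown_below([])
    annotated = gene_hits[(gene_hits[list(RANKS)] != "").any(axis=1)]
    n = len(annotated)
    if n == 0:
        return _unknown_below([])
    assigned: list[str] = []
    for rank in RANKS:
        counts = annotated[rank][annotated[rank] != ""].value_counts()
        if len(counts) and counts.iloc[0] > majority * n:
            assigned.append(str(counts.index[0]))
        else:
            break
    return _unknown_below(assigned)


def assign_source_environment(gene_hits: pd.DataFrame, majority: float = 0.5) -> str:
    """Strict-majority source environment over environment-labelled genes."""
    if gene_hits.empty or "environment" not in gene_hits:
        return "unknown"
    labels = gene_hits["environment"][gene_hits["environment"] != ""]
    known = labels.isin([e for e in ENVIRONMENT_VOCABULARY if e != "unknown"])
    if (~known).any():
        logger.warning("unrecognised environment labels mapped to unknown: %s",
                       sorted(labels[~known].unique()))
    labels = labels[known]
    if labels.empty:
        return "unknown"
    counts = labels.value_counts()
    if counts.iloc[0] > majority * len(labels):
        return str(counts.index[0])
    return "unknown"


def assign_votu_taxonomy(gene_taxonomy: pd.DataFrame, votus, majority: float = 0.5,
                         pool_member_genes: bool = False,
                         delimiter: str = "||") -> pd.DataFrame:
    """Lineage and source environment per vOTU.

    By default the vote runs over the representative contig's genes; with
    ``pool_member_genes`` every member's genes are pooled.
    """
    from halovir.io import strip_trim_suffix

    by_contig = dict(tuple(gene_taxonomy.groupby("contig_id")))
    rows = []
    for v in votus:
        if pool_member_genes:
            bases = {strip_trim_suffix(m, delimiter) for m in v.members}
        else:
            bases = {strip_trim_suffix(v.representative, delimiter)}
        hits = pd.concat([by_contig[b] for b in sorted(bases) if b in by_contig],
                         ignore_index=True) if any(b in by_contig for b in bases) \
            else pd.DataFrame(columns=gene_taxonomy.columns)
        lin = assign_taxonomy(hits, majority)
        env = assign_source_environment(hits, majority)
        rows.append({"votu_id": v.votu_id, **dict(zip(RANKS, lin.as_tuple())),
                     "environment": env})
    return pd.DataFrame(rows)
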
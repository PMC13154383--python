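"""Virus-host prediction filtering and the order-level bipartite network.

Host predictions from an in-silico predictor reference arbitrary genomes;
only matches between clustered vOTUs and quality-passing MAGs are retained.
MAG quality classes follow the usual completion/contamination cut-offs
(high: > 90% / < 5%; medium: > 50% / < 10%; otherwise fail, excluded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from halovir.clustering import VOtu
from halovir.io import strip_trim_suffix

logger = logging.getLogger("halovir")


@dataclass(frozen=True)
class MagRecord:
    mag_id: str
    completion: float
    contamination: float
    lineage: tuple[str, str, str, str]  # domain, phylum, class, order
    quality: str                        # high | medium | fail

    @property
    def host_class(self) -> str:
        return self.lineage[2]

    @property
    def host_order(self) -> str:
        return self.lineage[3]


@dataclass(frozen=True)
class HostEdge:
    votu_id: str
    mag_id: str
    host_order: str
    host_class: str
    host_phylum: str
    score: float
    votu_cluster: str = ""
    votu_site_class: str = ""


def classify_mags(mags: pd.DataFrame) -> list[MagRecord]:
    """Quality-class MAGs per the strict completion/contamination cut-offs.

    A MAG at exactly 90% completion is medium, not high; one at exactly 50%
    fails.  Out-of-range percentages are an error.
    """
    records = []
    n_fail = 0
    for _, row in mags.iterrows():
        comp, cont = float(row["completion"]), float(row["contamination"])
        if not (0 <= comp <= 100 and 0 <= cont <= 100):
            raise ValueError(f"{row['mag_id']}: completion/contamination outside [0, 100]")
        if comp > 90 and cont < 5:
            quality = "high"
        elif comp > 50 and cont < 10:
            quality = "medium"
        else:
            quality = "fail"
            n_fail += 1
        records.append(MagRecord(
            str(row["mag_id"]), comp, cont,
            (str(row["domain"]), str(row["phylum"]), str(row["class"]),
             str(row["order"])), quality))
    logger.info("classify_mags: %d MAGs, %d failed quality", len(records), n_fail)
    return records


def filter_predictions(predictions: pd.DataFrame, votus: list[VOtu],
                       mags: list[MagRecord],
                       votu_clusters: dict[str, str] | None = None,
                       votu_site_class: dict[str, str] | None = None,
                       delimiter: str = "||") -> list[HostEdge]:
    """Retain only virus-host matches between clustered vOTUs and good MAGs.

    The virus column may reference any member contig of a vOTU (trimmed
    variants included); predictions from unclustered contigs or to genomes
    that are not quality-passing MAGs are dropped (counted in the log).
    Duplicate vOTU-MAG pairs collapse to the best-scoring edge.
    """
    votu_of: dict[str, str] = {}
    for v in votus:
        for m in v.members:
            votu_of[strip_trim_suffix(m, delimiter)] = v.votu_id
    mag_by_id = {m.mag_id: m for m in mags if m.quality != "fail"}

    best: dict[tuple[str, str], HostEdge] = {}
    n_unknown_virus = n_bad_host = 0
    for _, row in predictions.iterrows():
        votu = votu_of.get(strip_trim_suffix(str(row["virus_id"]), delimiter))
        if votu is None:
            n_unknown_virus += 1
            continue
        mag = mag_by_id.get(str(row["host_genome"]))
        if mag is None:
            n_bad_host += 1
            continue
        score = float(row.get("score", 0.0))
        key = (votu, mag.mag_id)
        if key not in best or score > best[key].score:
            best[key] = HostEdge(
                votu_id=votu, mag_id=mag.mag_id, host_order=mag.host_order,
                host_class=mag.host_class, host_phylum=mag.lineage[1], score=score,
                votu_cluster=(votu_clusters or {}).get(votu, ""),
                votu_site_class=(votu_site_class or {}).get(votu, ""))
    logger.info("filter_predictions: %d edges kept, %d unclustered viruses, "
                "%d non-MAG or failing hosts dropped",
                len(best), n_unknown_virus, n_bad_host)
    return sorted(best.values(), key=lambda e: (e.votu_id, e.mag_id))


def build_network(edges: list[HostEdge]) -> nx.Graph:
    """Bipartite vOTU-MAG graph annotated with host order/class."""
    g = nx.Graph()
    for e in edges:
        g.add_node(e.votu_id, bipartite="votu", cluster=e.votu_cluster,
                   site_class=e.votu_site_class)
        g.add_node(e.mag_id, bipartite="mag", order=e.host_order,
                   host_class=e.host_class)
        g.add_edge(e.votu_id, e.mag_id, score=e.score)
    return g


def network_summary(edges: list[HostEdge],
                    mag_abundance: dict[str, float] | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Order-level summary of the virus-host network.

    Returns ``(per_order, multi_order, totals)``: MAG and vOTU counts (and
    total MAG relative abundance, when supplied) per host order; the vOTUs
    linked to more than one host order with the orders involved and whether
    they span phyla; and overall distinct vOTU/MAG counts.  Duplicated
    edges are idempotent and edge order is irrelevant.
    """
    uniq = {(e.votu_id, e.mag_id): e for e in edges}
    edges = sorted(uniq.values(), key=lambda e: (e.votu_id, e.mag_id))
    rows = []
    mag_abundance = mag_abundance or {}
    by_order: dict[str, dict[str, set]] = {}
    orders_of_votu: dict[str, set[str]] = {}
    phyla_of_votu: dict[str, set[str]] = {}
    for e in edges:
        d = by_order.setdefault(e.host_order, {"mags": set(), "votus": set()})
        d["mags"].add(e.mag_id)
        d["votus"].add(e.votu_id)
        orders_of_votu.setdefault(e.votu_id, set()).add(e.host_order)
        phyla_of_votu.setdefault(e.votu_id, set()).add(e.host_phylum)

    for order in sorted(by_order):
        d = by_order[order]
        rows.append({
            "host_order": order, "n_mags": len(d["mags"]),
            "n_votus": len(d["votus"]),
            "total_mag_relative_abundance": sum(mag_abundance.get(m, 0.0)
                                                for m in sorted(d["mags"])),
        })
    per_order = pd.DataFrame(rows, columns=["host_order", "n_mags", "n_votus",
                                            "total_mag_relative_abundance"])
    multi_rows = []
    for votu in sorted(orders_of_votu):
        orders = orders_of_votu[votu]
        if len(orders) > 1:
            multi_rows.append({
                "votu_id": votu, "n_orders": len(orders),
                "orders": ",".join(sorted(orders)),
                "spans_phyla": len(phyla_of_votu[votu]) > 1,
            })
    multi_order = pd.DataFrame(multi_rows, columns=["votu_id", "n_orders",
                                                    "orders", "spans_phyla"])
    totals = {"n_votus": len({e.votu_id for e in edges}),
              "n_mags": len({e.mag_id for e in edges}),
              "n_edges": len(edges)}
    return per_order, multi_order, totals
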
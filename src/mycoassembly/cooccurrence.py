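"""Spearman co-occurrence networks on top-abundance taxa.

Network "complexity" is summarized as node and edge counts after retaining
pairwise Spearman correlations with p below alpha and |rho| at or above a
threshold, computed per host group on the top-k taxa (typically genera) by
mean relative abundance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables_io import FeatureTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["aggregate_to_genus", "spearman_network", "NetworkSummary"]


def aggregate_to_genus(table: FeatureTable, taxon_map: dict) -> FeatureTable:
    """Sum ASV counts into genus-level counts per sample.

    ASVs without a mapping fall into an ``"unclassified"`` bucket. Column
    sums are conserved: total reads per sample are unchanged.
    """
    genera: dict[str, list[int]] = {}
    for j, asv in enumerate(table.asv_ids):
        genus = str(taxon_map.get(asv, "unclassified"))
        genera.setdefault(genus, []).append(j)
    names = sorted(genera)
    counts = np.column_stack([table.counts[:, genera[g]].sum(axis=1) for g in names])
    return FeatureTable(list(table.sample_ids), names, counts)


@dataclass
class NetworkSummary:
    group: str
    nodes: int
    edges: int
    edge_list: pd.DataFrame       # taxon_i, taxon_j, rho, p, sign
    retained_taxa: list[str]
    n_skipped_constant: int
    graph: nx.Graph

    def write_edges(self, path) -> None:
        self.edge_list.to_csv(path, sep="\t", index=False)


def spearman_network(
    table: FeatureTable,
    top_k: int = 30,
    rho_threshold: float = 0.5,
    alpha: float = 0.05,
    group: str = "all",
    drop_isolated: bool = False,
    use_relative: bool = True,
) -> NetworkSummary:
    """Co-occurrence network among the top-k most abundant taxa.

    Taxa are ranked by mean relative abundance across samples; edges keep
    pairs with Spearman p < alpha and |rho| >= rho_threshold (raw p, no
    multiple-testing correction by default — pass edges through your own
    correction if desired). Correlations are computed on relative
    abundances by default (``use_relative=False`` correlates raw counts,
    avoiding closure effects). Constant taxon vectors have undefined rank
    correlation; such pairs are skipped and counted.
    """
    if table.n_samples < 5:
        raise ValidationError("need at least 5 samples for a correlation network")
    if top_k > table.n_asvs:
        top_k = table.n_asvs
    rel = table.relative_abundance()
    order = np.argsort(rel.mean(axis=0))[::-1][:top_k]
    taxa = [table.asv_ids[j] for j in order]
    data = rel if use_relative else table.counts.astype(float)
    sub = data[:, order]

    rows = []
    skipped = 0
    for i in range(top_k):
        if np.ptp(sub[:, i]) == 0:
            skipped += top_k - 1 - i  # all its remaining pairs are undefined
            logger.info("constant taxon %s skipped in network", taxa[i])
            continue
        for j in range(i + 1, top_k):
            if np.ptp(sub[:, j]) == 0:
                skipped += 1
                continue
            rho, p = stats.spearmanr(sub[:, i], sub[:, j])
            if p < alpha and abs(rho) >= rho_threshold:
                rows.append({
                    "taxon_i": taxa[i], "taxon_j": taxa[j],
                    "rho": float(rho), "p": float(p),
                    "sign": "positive" if rho > 0 else "negative",
                })
    edges = pd.DataFrame(rows, columns=["taxon_i", "taxon_j", "rho", "p", "sign"])

    g = nx.Graph()
    g.add_nodes_from(taxa)
    for r in rows:
        g.add_edge(r["taxon_i"], r["taxon_j"], rho=r["rho"], p=r["p"], sign=r["sign"])
    if drop_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    return NetworkSummary(
        group=group,
        nodes=g.number_of_nodes(),
        edges=g.number_of_edges(),
        edge_list=edges,
        retained_taxa=taxa,
        n_skipped_constant=skipped,
        graph=g,
    )
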
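"""Topological characterization and comparison of the two condition-specific
networks.

Conventions (fixed here because directed-network centralities admit several):

* in-/out-degree on the directed TF->target graph; the summary's mean
  in-degree is links / #target-role nodes and mean out-degree is
  links / #TF-role nodes, so both identities ``mean_in_deg * |targets| =
  |links| = mean_out_deg * |tfs|`` hold exactly;
* betweenness via all-pairs shortest paths on the directed graph,
  unnormalized;
* clustering coefficient on the undirected projection (the directed
  TF->target graph is nearly bipartite and has almost no directed
  triangles);
* closeness of a node = (#nodes it reaches) / (sum of directed
  shortest-path distances to them), 0 for nodes reaching nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .grn import GRN

METRICS = ["in_deg", "out_deg", "betweenness", "clustering", "closeness"]


@dataclass
class TopologySummary:
    condition: str
    mean_in_deg: float
    mean_out_deg: float
    mean_betweenness: float
    mean_clustering: float
    mean_closeness: float
    per_node: pd.DataFrame


@dataclass
class LinkOverlap:
    overlapped: int
    a_specific: int
    b_specific: int


def _digraph(grn: GRN) -> nx.DiGraph:
    g = nx.DiGraph()
    for (tf, tg), eff in grn.links.items():
        g.add_edge(tf, tg, efficacy=float(eff))
    return g


def network_stats(grn: GRN) -> TopologySummary:
    """Per-node degree/betweenness/clustering/closeness and their means."""
    if not grn.links:
        raise ValueError("network_stats requires a non-empty GRN")
    g = _digraph(grn)
    nodes = sorted(g.nodes)
    betweenness = nx.betweenness_centrality(g, normalized=False)
    clustering = nx.clustering(g.to_undirected())
    closeness = {}
    for v in nodes:
        lengths = nx.single_source_shortest_path_length(g, v)
        total = sum(lengths.values())
        n_reach = len(lengths) - 1
        closeness[v] = n_reach / total if total > 0 else 0.0
    per_node = pd.DataFrame(
        {
            "node": nodes,
            "in_deg": [g.in_degree(v) for v in nodes],
            "out_deg": [g.out_degree(v) for v in nodes],
            "betweenness": [betweenness[v] for v in nodes],
            "clustering": [clustering[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
        }
    )
    return TopologySummary(
        condition=grn.condition,
        mean_in_deg=len(grn) / len(grn.targets),
        mean_out_deg=len(grn) / len(grn.tfs),
        mean_betweenness=float(per_node["betweenness"].mean()),
        mean_clustering=float(per_node["clustering"].mean()),
        mean_closeness=float(per_node["closeness"].mean()),
        per_node=per_node,
    )


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided rank-sum p-value: exact null for combined n <= 20 without
    ties, otherwise normal approximation with tie correction (and without
    continuity correction, so identical samples give p = 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0  # all values identical: the test is degenerate
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if len(x) + len(y) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return float(min(res.pvalue, 1.0))


def compare_topology(grn_a: GRN, grn_b: GRN) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per metric between the per-node
    metric distributions of the two networks."""
    stats_a, stats_b = network_stats(grn_a), network_stats(grn_b)
    if len(stats_a.per_node) < 2 or len(stats_b.per_node) < 2:
        raise ValueError("compare_topology requires >= 2 nodes per GRN")
    rows = []
    for metric in METRICS:
        p = _ranksum_p(
            stats_a.per_node[metric].to_numpy(), stats_b.per_node[metric].to_numpy()
        )
        rows.append({"metric": metric, "p_value": p})
    return pd.DataFrame(rows)


def summary_table(grn_a: GRN, grn_b: GRN) -> pd.DataFrame:
    """Mean metrics per condition plus the rank-sum p-value row."""
    rows = []
    for s in (network_stats(grn_a), network_stats(grn_b)):
        rows.append(
            {
                "condition": s.condition,
                "in_deg": s.mean_in_deg,
                "out_deg": s.mean_out_deg,
                "betweenness": s.mean_betweenness,
                "clustering": s.mean_clustering,
                "closeness": s.mean_closeness,
            }
        )
    comp = compare_topology(grn_a, grn_b).set_index("metric")["p_value"]
    rows.append(
        {
            "condition": f"{grn_a.condition} vs {grn_b.condition} (p)",
            "in_deg": comp["in_deg"],
            "out_deg": comp["out_deg"],
            "betweenness": comp["betweenness"],
            "clustering": comp["clustering"],
            "closeness": comp["closeness"],
        }
    )
    return pd.DataFrame(rows)


def classify_links(grn_a: GRN, grn_b: GRN) -> LinkOverlap:
    """Overlapped vs condition-specific link counts (efficacies ignored)."""
    a, b = set(grn_a.links), set(grn_b.links)
    return LinkOverlap(
        overlapped=len(a & b), a_specific=len(a - b), b_specific=len(b - a)
    )
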
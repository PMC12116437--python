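"""Centrality analysis and hub classification on the functional graph.

Degree centrality is the raw incident-edge count; betweenness is the
unnormalized sum over unordered distinct node pairs of the fraction of
shortest paths passing through the node (endpoints excluded; unreachable
pairs contribute nothing).  Edge signs are ignored — the graph is treated as
unweighted and undirected for all centrality computation.

Hubs are regions strictly above the 80th percentile (linear interpolation
between order statistics) of *both* degree and betweenness; an alternative
sum rule (min-max rescaled degree + betweenness above the 80th percentile of
the sums) is available.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "degree_centrality",
    "betweenness_centrality",
    "centrality_table",
    "classify_hubs",
    "compare_degree_distributions",
]


def degree_centrality(g: nx.Graph) -> dict[str, int]:
    """Incident edge count per node (sign-blind)."""
    return {n: int(d) for n, d in g.degree()}


def betweenness_centrality(g: nx.Graph) -> dict[str, float]:
    """Unnormalized shortest-path betweenness over unordered pairs."""
    return {n: float(b) for n, b in
            nx.betweenness_centrality(g, normalized=False).items()}


def _strict_quantile_rank(values: np.ndarray) -> np.ndarray:
    """Fraction of nodes strictly below each value."""
    v = np.asarray(values, dtype=float)
    return (v[:, None] > v[None, :]).mean(axis=1)


def centrality_table(g: nx.Graph, hub_quantile: float = 0.8,
                     hub_rule: str = "both") -> pd.DataFrame:
    """Per-region centralities, quantile ranks and hub flags for one graph."""
    nodes = list(g.nodes)
    deg = np.array([g.degree(n) for n in nodes], dtype=float)
    btw_map = betweenness_centrality(g)
    btw = np.array([btw_map[n] for n in nodes])
    table = pd.DataFrame(
        {
            "region": nodes,
            "degree": deg.astype(int),
            "betweenness": btw,
            "degree_q": _strict_quantile_rank(deg),
            "betweenness_q": _strict_quantile_rank(btw),
        }
    )
    hubs = classify_hubs(table, hub_quantile=hub_quantile, rule=hub_rule)
    table["is_hub"] = table["region"].isin(hubs)
    return table


def classify_hubs(
    table: pd.DataFrame, hub_quantile: float = 0.8, rule: str = "both"
) -> set[str]:
    """Regions above the hub quantile of centrality.

    ``rule="both"``: strictly above the quantile of degree AND betweenness.
    ``rule="sum"``: degree and betweenness min-max rescaled to [0, 1], hub iff
    their sum is strictly above the quantile of the sums.
    """
    if table.empty:
        raise ValueError("centrality table is empty")
    deg = table["degree"].to_numpy(dtype=float)
    btw = table["betweenness"].to_numpy(dtype=float)
    if rule == "both":
        qd = np.quantile(deg, hub_quantile)  # linear interpolation (default)
        qb = np.quantile(btw, hub_quantile)
        keep = (deg > qd) & (btw > qb)
    elif rule == "sum":
        def rescale(v: np.ndarray) -> np.ndarray:
            span = v.max() - v.min()
            return np.zeros_like(v) if span == 0 else (v - v.min()) / span
        s = rescale(deg) + rescale(btw)
        keep = s > np.quantile(s, hub_quantile)
    else:
        raise ValueError(f"unknown hub rule {rule!r}")
    return set(table.loc[keep, "region"])


def compare_degree_distributions(
    a: pd.DataFrame, b: pd.DataFrame
) -> tuple[float, float]:
    """Mann–Whitney (Wilcoxon rank-sum) comparison of per-region degrees.

    Returns (W, p): the rank-sum statistic of the first table's degrees and a
    two-sided p-value from the tie-corrected normal approximation.
    """
    x = a["degree"].to_numpy(dtype=float)
    y = b["degree"].to_numpy(dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty centrality table")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
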
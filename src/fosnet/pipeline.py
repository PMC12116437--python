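"""End-to-end orchestration: counts → densities → stats → networks → hubs.

``run_pipeline`` executes every stage on a count table + anatomical
adjacency, writes all result tables under the configured output directory and
returns them in memory.  All outputs are deterministic functions of the
inputs and configuration, so rerunning a config yields byte-identical files;
a machine-readable manifest records inputs, thresholds, seed and versions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .activation import fit_network_model, region_stats_table
from .config import PipelineConfig
from .connectome import (
    CorrelationMatrix,
    compare_connected_unconnected,
    correlation_matrix,
    mask_anatomical,
    threshold_edges,
)
from .density import DensityTable, compute_density
from .io import (
    read_adjacency,
    read_count_table,
    read_network_map,
    write_edge_list,
    write_graphml,
    write_manifest,
)
from .network import centrality_table, classify_hubs, compare_degree_distributions

log = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    density: DensityTable
    region_stats: pd.DataFrame
    network_stats: pd.DataFrame | None
    correlations: dict[str, CorrelationMatrix]
    masked: dict[str, CorrelationMatrix]
    graphs: dict[str, nx.Graph]
    centrality: dict[str, pd.DataFrame]
    hubs: dict[str, set[str]]
    report: dict[str, Any]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    for attr in ("counts_path", "adjacency_path"):
        p = Path(getattr(config, attr))
        if not p.exists():
            raise FileNotFoundError(f"pipeline config: {attr} does not exist: {p}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    counts = read_count_table(config.counts_path)
    adjacency = read_adjacency(config.adjacency_path)
    groups = list(dict.fromkeys(counts["group"]))
    treated = groups[-1]  # convention: second group label is the treated one

    # -- stage 1: densities ---------------------------------------------------
    density = compute_density(counts)
    density.to_csv(out / "density.csv")

    # -- stage 2: per-region activation statistics ----------------------------
    region_stats = region_stats_table(
        counts, treated_group=treated, adjust_method=config.adjust_method
    )
    region_stats.to_csv(out / "region_stats.csv", index=False)

    network_stats = None
    if config.network_map_path:
        nmap = read_network_map(config.network_map_path)
        rows = []
        for net in dict.fromkeys(nmap.values()):
            members = [r for r, n in nmap.items() if n == net]
            if len(members) < 2:
                continue
            res = fit_network_model(
                counts[counts["region"].isin(members)], network=net,
                treated_group=treated,
            )
            rows.append(
                {"network": net, "chi2": res.chi2, "df": res.df, "p": res.p,
                 "lfc": res.treatment_lfc_estimate, "n_obs": res.n_obs}
            )
        network_stats = pd.DataFrame(rows)
        network_stats.to_csv(out / "network_stats.csv", index=False)

    # -- stage 3: per-group functional connectomes ----------------------------
    correlations: dict[str, CorrelationMatrix] = {}
    masked: dict[str, CorrelationMatrix] = {}
    graphs: dict[str, nx.Graph] = {}
    centrality: dict[str, pd.DataFrame] = {}
    hubs: dict[str, set[str]] = {}
    pair_tests: dict[str, dict[str, float]] = {}
    for g in groups:
        corr = correlation_matrix(density.restrict_group(g), group=g)
        corr.write(out, prefix=f"corr_{g}_")
        correlations[g] = corr
        t, dfree, p = compare_connected_unconnected(
            corr, adjacency, value=config.pair_value
        )
        pair_tests[g] = {"t": t, "df": dfree, "p": p}
        m = mask_anatomical(corr, adjacency)
        masked[g] = m
        graph = threshold_edges(m, r2_min=config.r2_min, p_max=config.p_max)
        graphs[g] = graph
        write_edge_list(graph, out / f"edges_{g}.csv")
        write_graphml(graph, out / f"graph_{g}.graphml")

        # -- stage 4: centralities and hubs -----------------------------------
        ct = centrality_table(
            graph, hub_quantile=config.hub_quantile, hub_rule=config.hub_rule
        )
        ct.to_csv(out / f"centrality_{g}.csv", index=False)
        centrality[g] = ct
        hubs[g] = classify_hubs(ct, config.hub_quantile, config.hub_rule)

    report: dict[str, Any] = {
        "groups": groups,
        "hubs": {g: sorted(h) for g, h in hubs.items()},
        "edge_counts": {g: graphs[g].number_of_edges() for g in groups},
        "connected_vs_unconnected": pair_tests,
    }
    if len(groups) == 2:
        w, p = compare_degree_distributions(
            centrality[groups[1]], centrality[groups[0]]
        )
        report["degree_comparison"] = {
            "first": groups[1], "second": groups[0], "W": w, "p": p,
        }
    manifest_cfg = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    write_manifest(
        {
            "fosnet_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "config": manifest_cfg,
        },
        out / "manifest.json",
    )
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return PipelineResult(
        density=density,
        region_stats=region_stats,
        network_stats=network_stats,
        correlations=correlations,
        masked=masked,
        graphs=graphs,
        centrality=centrality,
        hubs=hubs,
        report=report,
    )
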
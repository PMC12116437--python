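"""Readers and writers for the pipeline's plain-text formats.

Every writer has a paired reader that round-trips values at full precision
(floats are written with ``repr`` precision via pandas' default formatting).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

from .simulate import COUNT_COLUMNS

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_adjacency",
    "write_adjacency",
    "read_network_map",
    "write_network_map",
    "write_edge_list",
    "read_edge_list",
    "write_graphml",
    "write_manifest",
]


class IOError_(ValueError):
    pass


def write_count_table(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, index=False)


def read_count_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError_(f"count table not found: {path}")
    df = pd.read_csv(path)
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise IOError_(f"count table {path} lacks columns {sorted(missing)}")
    return df


def write_adjacency(adj: pd.DataFrame, path: str | Path) -> None:
    adj.to_csv(path)


def read_adjacency(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError_(f"adjacency matrix not found: {path}")
    adj = pd.read_csv(path, index_col=0)
    adj.columns.name = None
    return adj.astype(int)


def write_network_map(networks: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"region": list(networks), "network": list(networks.values())}
    ).to_csv(path, index=False)


def read_network_map(path: str | Path) -> dict[str, str]:
    path = Path(path)
    if not path.exists():
        raise IOError_(f"network membership map not found: {path}")
    df = pd.read_csv(path)
    return dict(zip(df["region"], df["network"]))


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    rows = [
        {
            "region_a": u,
            "region_b": v,
            "sign": d["sign"],
            "weight": d["weight"],
            "r": d.get("r", float("nan")),
        }
        for u, v, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(
        rows, columns=["region_a", "region_b", "sign", "weight", "r"]
    ).to_csv(path, index=False)


def read_edge_list(path: str | Path) -> nx.Graph:
    df = pd.read_csv(path)
    g = nx.Graph()
    for row in df.itertuples(index=False):
        g.add_edge(row.region_a, row.region_b, sign=row.sign,
                   weight=float(row.weight), r=float(row.r))
    return g


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, path)


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True))
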
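#!/usr/bin/env python
"""Group-wise functional connectome reconstruction.

Computes per-group Pearson correlation matrices of regional densities,
verifies that anatomically connected pairs correlate more strongly than
unconnected pairs (Welch test), masks the matrices with the anatomical
adjacency, and thresholds (|R²| > 0.7, p < 0.05) to the functional graphs.
Reads results/data/, writes results/connectome/.
"""

from pathlib import Path

from fosnet import (
    compare_connected_unconnected,
    compute_density,
    correlation_matrix,
    mask_anatomical,
    threshold_edges,
)
from fosnet.io import (
    read_adjacency,
    read_count_table,
    write_edge_list,
    write_graphml,
)

DATA = Path("results/data")
OUT = Path("results/connectome")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    counts = read_count_table(DATA / "counts_hub.csv")
    adjacency = read_adjacency(DATA / "adjacency.csv")
    density = compute_density(counts)
    density.to_csv(OUT / "density.csv")

    for group in density.groups:
        corr = correlation_matrix(density.restrict_group(group), group=group)
        corr.write(OUT, prefix=f"corr_{group}_")
        t, df, p = compare_connected_unconnected(corr, adjacency)
        print(f"[{group}] connected vs unconnected pairs: "
              f"t = {t:.3f}, df = {df:.1f}, p = {p:.4g}")
        graph = threshold_edges(mask_anatomical(corr, adjacency))
        write_edge_list(graph, OUT / f"edges_{group}.csv")
        write_graphml(graph, OUT / f"graph_{group}.graphml")
        pos = sum(1 for *_, d in graph.edges(data=True) if d["sign"] == "+")
        print(f"[{group}] functional graph: {graph.number_of_edges()} edges "
              f"({pos} positive, {graph.number_of_edges() - pos} negative)")


if __name__ == "__main__":
    main()
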
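#!/usr/bin/env python
"""Simulate the two demonstration studies.

Both studies share the design of the emulated experiment: 10 CTR + 11 VPA
pups from 14 litters, 36 brain regions, bilateral per-slide c-Fos counts with
negative-binomial noise and a log-area offset structure.

* **Activation study** (``results/data/counts_activation.csv``) — default
  conditions: independent latent activations, modest litter effects, and the
  treatment scenario in which VPA offspring show reduced isolation-induced
  activation in reward/social/stress nuclei (log fold changes of −0.5 for the
  strongly affected regions, −0.25 for marginal ones).  Used by the
  regional/network activation statistics (02).
* **Hub study** (``results/data/counts_hub.csv``) — the interpeduncular
  nucleus (IPN) is a planted coactivation hub: latent correlation 0.9 to
  every region routed through a single shared factor (latent scale 2.5 so the
  observed density correlations match), and an anatomical connectome that
  wires IPN to all other regions over an Erdős–Rényi background.  Used by the
  connectome reconstruction and hub analysis (03, 04).
"""

from pathlib import Path

import fosnet
from fosnet.config import hub_factor_corr
from fosnet.io import write_adjacency, write_count_table, write_network_map
from fosnet.regions import DEFAULT_NETWORKS

SEED = 2026
HUB = "IPN"
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    regions = list(fosnet.StudyConfig.default(seed=0).regions)

    activation_cfg = fosnet.StudyConfig.default(seed=SEED)
    counts_act, _ = fosnet.generate_study(activation_cfg)
    write_count_table(counts_act, OUT / "counts_activation.csv")
    activation_cfg.to_yaml(OUT / "config_activation.yaml")

    hub_cfg = fosnet.StudyConfig.default(
        seed=SEED + 1,
        latent_corr=hub_factor_corr(regions, HUB, 0.9),
        latent_scale=2.5,
        planted_hub=HUB,
    )
    counts_hub, truth = fosnet.generate_study(hub_cfg)
    adjacency = fosnet.generate_anatomical_connectome(
        regions, edge_density=0.3, planted_hub=HUB, seed=SEED + 2
    )
    write_count_table(counts_hub, OUT / "counts_hub.csv")
    write_adjacency(adjacency, OUT / "adjacency.csv")
    truth.to_json(OUT / "truth.json")
    hub_cfg.to_yaml(OUT / "config_hub.yaml")
    write_network_map(DEFAULT_NETWORKS, OUT / "networks.csv")

    n_subj = counts_act["subject_id"].nunique()
    print(f"activation study: {n_subj} subjects × {len(regions)} regions "
          f"({len(counts_act)} slide-level records)")
    print(f"hub study: planted hub {HUB}; anatomical edges: "
          f"{int(adjacency.to_numpy().sum() // 2)} "
          f"(hub wired to all {len(regions) - 1} other regions)")
    print(f"outputs in {OUT}/")


if __name__ == "__main__":
    main()
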
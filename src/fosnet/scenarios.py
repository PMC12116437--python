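"""Frozen simulation scenarios used for validating the pipeline.

Each scenario is one replicate of a study condition with known ground truth:

* ``null_region_replicate`` — a single region with zero treatment effect at
  study scale (10 + 11 subjects, 14 litters), for type-I error measurement.
* ``lfc_recovery_replicate`` — the same design with a true treatment log fold
  change of −0.7, for parameter-recovery measurement.
* ``hub_recovery_replicate`` — a planted anatomical-and-latent hub: the hub
  is wired to every other region (star anatomy) and carries latent
  correlation 0.9 to all regions through a single shared factor; the latent
  scale (2.5) is chosen so observed density correlations match the planted
  0.9 rather than an attenuated value.  Returns the hub set of the control
  graph (n = 10).
* ``connectivity_replicate`` — latent correlation supported exactly on an
  Erdős–Rényi anatomical adjacency (``I + wA`` at the maximum
  positive-semidefinite support strength), null treatment effect; the
  connected-vs-unconnected Welch test runs on the full-cohort correlation
  matrix (n = 21).  With ``shuffled=True`` the adjacency labels are permuted,
  which should destroy the effect.

Seeds are plain integers; derive replicate seeds from a master seed with
``numpy.random.SeedSequence`` when running batches.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .activation import fit_region_model
from .config import StudyConfig, adjacency_supported_corr, hub_factor_corr
from .connectome import compare_connected_unconnected, correlation_matrix, \
    mask_anatomical, threshold_edges
from .density import compute_density
from .network import centrality_table, classify_hubs
from .simulate import generate_anatomical_connectome, generate_study

__all__ = [
    "null_region_replicate",
    "lfc_recovery_replicate",
    "hub_recovery_replicate",
    "connectivity_replicate",
]

HUB_LATENT_SCALE = 2.5
HUB_RHO = 0.9
SUPPORT_STRENGTH = 0.9


def _single_region_config(seed: int, lfc: float) -> StudyConfig:
    return StudyConfig.default(
        seed=seed,
        regions=["CPU"],
        treatment_log_fold_change={"CPU": lfc},
    )


def null_region_replicate(seed: int) -> tuple[float, float]:
    """(p, lfc estimate) of the treatment LR test when the true effect is 0."""
    counts, _ = generate_study(_single_region_config(seed, 0.0))
    res = fit_region_model(counts)
    return res.p, res.treatment_lfc_estimate


def lfc_recovery_replicate(seed: int, true_lfc: float = -0.7) -> float:
    """Estimated treatment log fold change when the true value is ``true_lfc``."""
    counts, _ = generate_study(_single_region_config(seed, true_lfc))
    res = fit_region_model(counts)
    return res.treatment_lfc_estimate


def hub_recovery_replicate(
    seed: int, hub: str = "IPN", group: str = "CTR",
    hub_quantile: float = 0.8, rule: str = "both",
) -> set[str]:
    """Hub set recovered from one planted-hub study (evaluated on one group)."""
    regions = list(StudyConfig.default(seed=0).regions)
    cfg = StudyConfig.default(
        seed=seed,
        latent_corr=hub_factor_corr(regions, hub, HUB_RHO),
        latent_scale=HUB_LATENT_SCALE,
        planted_hub=hub,
    )
    counts, _ = generate_study(cfg)
    adj = generate_anatomical_connectome(
        cfg.regions, edge_density=0.0, planted_hub=hub, seed=seed + 1
    )
    dens = compute_density(counts)
    corr = correlation_matrix(dens.restrict_group(group), group=group)
    graph = threshold_edges(mask_anatomical(corr, adj))
    table = centrality_table(graph, hub_quantile=hub_quantile, hub_rule=rule)
    return classify_hubs(table, hub_quantile=hub_quantile, rule=rule)


def connectivity_replicate(
    seed: int, shuffled: bool = False, edge_density: float = 0.3
) -> tuple[float, float]:
    """(t, p) of the connected-vs-unconnected Welch test for one replicate."""
    regions = list(StudyConfig.default(seed=0).regions)
    adj = generate_anatomical_connectome(regions, edge_density, seed=seed + 100_000)
    cfg = StudyConfig.default(
        seed=seed,
        latent_corr=adjacency_supported_corr(adj, SUPPORT_STRENGTH),
        latent_scale=HUB_LATENT_SCALE,
        treatment_log_fold_change={r: 0.0 for r in regions},
    )
    counts, _ = generate_study(cfg)
    dens = compute_density(counts)
    corr = correlation_matrix(dens.densities, group="all")
    if shuffled:
        rng = np.random.default_rng(seed + 200_000)
        perm = rng.permutation(len(regions))
        adj = pd.DataFrame(
            adj.to_numpy()[np.ix_(perm, perm)], index=regions, columns=regions
        )
    t, _, p = compare_connected_unconnected(corr, adj)
    return t, p
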
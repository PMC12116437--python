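"""Synthetic study generator.

Emulates the statistical structure of a two-group (control vs prenatally
treated) c-Fos mapping experiment: subjects nested in litters, bilateral
per-slide counts over a fixed region panel, negative-binomial count noise,
and a latent multivariate-normal activation field that induces controllable
cross-region correlation on the log-mean scale (Gaussian-copula-like, so
counts stay marginally NB).

Generative model per subject ``s`` in group ``g`` and region ``r``::

    b_litter(s)  ~ Normal(0, litter_sd²)
    z_s          ~ MVN(0, latent_corr[g])              (one draw per subject)
    log μ_sr     = baseline_r + lfc_r·[s treated] + b_litter(s) + latent_scale·z_sr
    total_sr     ~ NegBin(mean = μ_sr · area_r, size = nb_dispersion)
    slide/hemisphere counts: multinomial split of total_sr, equal probabilities

The NB "size" parameterization is variance = μ + μ²/size throughout the
package.  A per-individual random intercept is not drawn separately: with a
single aggregated observation per subject and region it is not identifiable
from NB overdispersion, which absorbs it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Any

import json

import numpy as np
import pandas as pd

from .config import ConfigError, StudyConfig

__all__ = [
    "COUNT_COLUMNS",
    "SimulationTruth",
    "generate_anatomical_connectome",
    "generate_study",
]

COUNT_COLUMNS = [
    "subject_id",
    "group",
    "litter_id",
    "region",
    "hemisphere",
    "slide_index",
    "count",
    "area_mm2",
]


@dataclass
class SimulationTruth:
    """Ground truth of one synthetic study, for recovery tests."""

    planted_hub: str | None
    latent_corr: dict[str, pd.DataFrame]
    treatment_log_fold_change: dict[str, float]
    litter_intercepts: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        d: dict[str, Any] = {
            "planted_hub": self.planted_hub,
            "treatment_log_fold_change": self.treatment_log_fold_change,
            "litter_intercepts": self.litter_intercepts,
            "latent_corr": {
                g: m.to_numpy().tolist() for g, m in self.latent_corr.items()
            },
        }
        Path(path).write_text(json.dumps(d, indent=1))


def generate_anatomical_connectome(
    regions: list[str],
    edge_density: float,
    planted_hub: str | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Random anatomical adjacency (stand-in for an axonal-tracing connectome).

    Erdős–Rényi at ``edge_density``; when ``planted_hub`` is given, that
    region is additionally wired to every other region.  ``edge_density = 0``
    (a pure star around the hub) is valid only with a planted hub.
    """
    if planted_hub is not None and planted_hub not in regions:
        raise ConfigError(f"planted hub {planted_hub!r} is not a region label")
    lo = 0.0 if planted_hub is not None else None
    if not (0.0 < edge_density < 1.0 or (lo is not None and edge_density == 0.0)):
        raise ConfigError(f"edge_density={edge_density} must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(regions)
    upper = rng.random((n, n)) < edge_density
    adj = np.triu(upper, k=1)
    adj = (adj | adj.T).astype(int)
    if planted_hub is not None:
        h = regions.index(planted_hub)
        adj[h, :] = 1
        adj[:, h] = 1
    np.fill_diagonal(adj, 0)
    return pd.DataFrame(adj, index=regions, columns=regions)


def generate_study(config: StudyConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw one complete study: tidy count table + ground-truth record."""
    rng = np.random.default_rng(config.seed)
    subjects = config.subjects()
    regions = config.regions
    k = config.nb_dispersion

    litter_ids = sorted(subjects["litter_id"].unique())
    litter_b = dict(
        zip(litter_ids, rng.normal(0.0, config.litter_sd, size=len(litter_ids)))
    )

    # Cholesky of each group's latent correlation (PSD-safe via tiny jitter)
    chol = {}
    for g in config.group_labels:
        m = config.latent_corr[g].to_numpy()
        chol[g] = np.linalg.cholesky(m + 1e-10 * np.eye(len(m)))

    rows: list[dict[str, Any]] = []
    for subj in subjects.itertuples(index=False):
        g = subj.group
        treated = 1.0 if g == config.treated_group else 0.0
        z = chol[g] @ rng.standard_normal(len(regions))
        for j, r in enumerate(regions):
            area = config.region_area[r]
            log_mu = (
                config.baseline_log_density[r]
                + config.treatment_log_fold_change[r] * treated
                + litter_b[subj.litter_id]
                + config.latent_scale * z[j]
            )
            mean_count = np.exp(log_mu) * area
            total = int(rng.negative_binomial(k, k / (k + mean_count)))
            n_slides = config.slides_per_region[r]
            cells = 2 * n_slides  # hemispheres × slides, equal probabilities
            split = rng.multinomial(total, np.full(cells, 1.0 / cells))
            cell_area = area / cells
            i = 0
            for slide in range(n_slides):
                for hemi in ("left", "right"):
                    rows.append(
                        {
                            "subject_id": subj.subject_id,
                            "group": g,
                            "litter_id": subj.litter_id,
                            "region": r,
                            "hemisphere": hemi,
                            "slide_index": slide,
                            "count": int(split[i]),
                            "area_mm2": cell_area,
                        }
                    )
                    i += 1

    counts = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    truth = SimulationTruth(
        planted_hub=config.planted_hub,
        latent_corr=config.latent_corr,
        treatment_log_fold_change=dict(config.treatment_log_fold_change),
        litter_intercepts={l: float(b) for l, b in litter_b.items()},
    )
    return counts, truth
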
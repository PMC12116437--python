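"""Study and pipeline configuration objects.

``StudyConfig`` fixes every knob of the synthetic study generator: design
(group sizes, litters), per-region geometry (ROI areas), the log-scale
activation model (baselines, treatment log fold changes, litter SD, latent
cross-region correlation) and the count noise (negative-binomial size).
``PipelineConfig`` carries the analysis-side thresholds.

Correlation matrices can be given explicitly, or built with the helpers
:func:`identity_corr`, :func:`hub_factor_corr` (a one-factor structure that
routes all cross-region correlation through a single hub region) and
:func:`adjacency_supported_corr` (correlation supported only on an anatomical
adjacency).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .regions import (
    DEFAULT_AREAS,
    DEFAULT_BASELINE_DENSITY,
    DEFAULT_REGIONS,
    DEFAULT_TREATMENT_LFC,
)

__all__ = [
    "StudyConfig",
    "PipelineConfig",
    "identity_corr",
    "hub_factor_corr",
    "adjacency_supported_corr",
    "check_correlation",
]

PSD_TOL = 1e-8


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


def identity_corr(regions: list[str]) -> pd.DataFrame:
    """Independent latent activations (no cross-region coupling)."""
    return pd.DataFrame(np.eye(len(regions)), index=regions, columns=regions)


def hub_factor_corr(regions: list[str], hub: str, rho: float = 0.9) -> pd.DataFrame:
    """One-factor latent correlation routed through ``hub``.

    The hub loads 1.0 on a shared factor and every other region loads ``rho``,
    so corr(hub, other) = rho and corr(other, other') = rho² — the indirect
    coupling that anatomical masking is designed to discount.
    """
    if hub not in regions:
        raise ConfigError(f"planted hub {hub!r} is not one of the study regions")
    if not 0.0 <= rho < 1.0:
        raise ConfigError(f"hub correlation rho={rho} outside [0, 1)")
    loadings = np.full(len(regions), rho)
    loadings[regions.index(hub)] = 1.0
    c = np.outer(loadings, loadings)
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=regions, columns=regions)


def adjacency_supported_corr(
    adjacency: pd.DataFrame, strength_frac: float = 0.9
) -> pd.DataFrame:
    """Latent correlation supported exactly on an anatomical adjacency.

    Builds ``I + w·A`` with ``w = strength_frac / |λ_min(A)|`` so the result is
    positive semidefinite while anatomically unconnected pairs have zero latent
    correlation.
    """
    a = adjacency.to_numpy(dtype=float)
    if not np.array_equal(a, a.T):
        raise ConfigError("adjacency must be symmetric")
    lam_min = float(np.linalg.eigvalsh(a)[0])
    w = 0.0 if lam_min >= -PSD_TOL else strength_frac / abs(lam_min)
    c = np.eye(len(a)) + w * a
    return pd.DataFrame(c, index=adjacency.index, columns=adjacency.columns)


def check_correlation(c: pd.DataFrame, name: str = "latent_corr") -> None:
    """Validate symmetry, unit diagonal and positive semidefiniteness."""
    m = c.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or list(c.index) != list(c.columns):
        raise ConfigError(f"{name}: matrix labels are not square/consistent")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ConfigError(f"{name}: matrix is not symmetric")
    if not np.allclose(np.diag(m), 1.0, atol=1e-10):
        raise ConfigError(f"{name}: diagonal is not 1")
    if float(np.linalg.eigvalsh(m)[0]) < -PSD_TOL:
        raise ConfigError(f"{name}: matrix is not positive semidefinite")


@dataclass
class StudyConfig:
    """Full specification of one synthetic two-group c-Fos study."""

    n_per_group: dict[str, int]
    n_litters: int
    regions: list[str]
    region_area: dict[str, float]
    baseline_log_density: dict[str, float]
    treatment_log_fold_change: dict[str, float]
    litter_sd: float
    nb_dispersion: float
    latent_scale: float
    #: per-group latent correlation (group label -> DataFrame); a single
    #: matrix may be supplied and is shared by both groups
    latent_corr: dict[str, pd.DataFrame]
    slides_per_region: dict[str, int]
    seed: int
    group_labels: tuple[str, str] = ("CTR", "VPA")
    treated_group: str = "VPA"
    planted_hub: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.latent_corr, pd.DataFrame):
            self.latent_corr = {g: self.latent_corr for g in self.group_labels}
        self.validate()

    def validate(self) -> None:
        if len(self.group_labels) != 2:
            raise ConfigError("exactly two group labels are required")
        for g in self.group_labels:
            if self.n_per_group.get(g, 0) < 1:
                raise ConfigError(f"n_per_group missing/invalid for group {g!r}")
        total = sum(self.n_per_group[g] for g in self.group_labels)
        if not 1 <= self.n_litters <= total:
            raise ConfigError(
                f"n_litters={self.n_litters} must be in [1, total subjects={total}]"
            )
        if self.treated_group not in self.group_labels:
            raise ConfigError(f"treated_group {self.treated_group!r} not a group label")
        if len(set(self.regions)) != len(self.regions):
            raise ConfigError("duplicate region labels")
        for r in self.regions:
            if self.region_area.get(r, -1.0) <= 0:
                raise ConfigError(f"region_area must be positive for region {r!r}")
            if r not in self.baseline_log_density:
                raise ConfigError(f"baseline_log_density missing region {r!r}")
            if self.slides_per_region.get(r, 0) < 1:
                raise ConfigError(f"slides_per_region must be ≥ 1 for region {r!r}")
        if self.litter_sd < 0:
            raise ConfigError("litter_sd must be nonnegative")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion (NB size) must be positive")
        if self.latent_scale < 0:
            raise ConfigError("latent_scale must be nonnegative")
        if self.planted_hub is not None and self.planted_hub not in self.regions:
            raise ConfigError(f"planted hub {self.planted_hub!r} not in regions")
        for g in self.group_labels:
            c = self.latent_corr[g]
            if list(c.index) != list(self.regions):
                c = c.loc[self.regions, self.regions]
                self.latent_corr[g] = c
            check_correlation(c, name=f"latent_corr[{g}]")

    # -- construction helpers -------------------------------------------------

    @classmethod
    def default(cls, seed: int = 0, **overrides: Any) -> "StudyConfig":
        """The default study: 10 CTR + 11 VPA pups from 14 litters, 36 regions."""
        regions = list(overrides.pop("regions", DEFAULT_REGIONS))
        base = dict(
            n_per_group={"CTR": 10, "VPA": 11},
            n_litters=14,
            regions=regions,
            region_area={r: DEFAULT_AREAS.get(r, 0.5) for r in regions},
            baseline_log_density={
                r: float(np.log(DEFAULT_BASELINE_DENSITY.get(r, 100.0)))
                for r in regions
            },
            treatment_log_fold_change={
                r: DEFAULT_TREATMENT_LFC.get(r, 0.0) for r in regions
            },
            litter_sd=0.15,
            nb_dispersion=8.0,
            latent_scale=0.3,
            latent_corr=identity_corr(regions),
            slides_per_region={
                r: (2 if DEFAULT_AREAS.get(r, 0.5) >= 1.0 else 1) for r in regions
            },
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)

    def subjects(self) -> pd.DataFrame:
        """Deterministic subject roster: subject_id, group, litter_id.

        Litters are treatment-specific (the exposure is prenatal, applied to
        the dam), split as evenly as possible between groups; subjects are
        assigned round-robin within their group's litters.
        """
        g1, g2 = self.group_labels
        n_l1 = self.n_litters // 2 + self.n_litters % 2
        litters = {g1: [], g2: []}
        for i in range(self.n_litters):
            litters[g1 if i < n_l1 else g2].append(f"L{i + 1:02d}")
        rows = []
        for g in self.group_labels:
            pool = litters[g] if litters[g] else litters[g1]
            for j in range(self.n_per_group[g]):
                rows.append(
                    {
                        "subject_id": f"{g}{j + 1:02d}",
                        "group": g,
                        "litter_id": pool[j % len(pool)],
                    }
                )
        return pd.DataFrame(rows)

    # -- (de)serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["group_labels"] = list(self.group_labels)
        d["latent_corr"] = {
            g: [[float(v) for v in row] for row in self.latent_corr[g].to_numpy()]
            for g in self.group_labels
        }
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "StudyConfig":
        d = dict(d)
        if "seed" not in d:
            raise ConfigError("study config must carry an explicit seed")
        d["group_labels"] = tuple(d.get("group_labels", ("CTR", "VPA")))
        regions = list(d["regions"])
        lc = d.get("latent_corr", "identity")
        d["latent_corr"] = _parse_latent_corr(lc, regions, d["group_labels"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _parse_latent_corr(
    entry: Any, regions: list[str], groups: tuple[str, str]
) -> dict[str, pd.DataFrame]:
    def one(s: Any) -> pd.DataFrame:
        if isinstance(s, str):
            if s == "identity":
                return identity_corr(regions)
            raise ConfigError(f"unknown latent_corr shorthand {s!r}")
        if isinstance(s, Mapping) and s.get("type") == "one_factor":
            return hub_factor_corr(regions, s["hub"], float(s.get("rho", 0.9)))
        return pd.DataFrame(np.asarray(s, dtype=float), index=regions, columns=regions)

    if isinstance(entry, Mapping) and set(entry) >= set(groups):
        return {g: one(entry[g]) for g in groups}
    shared = one(entry)
    return {g: shared for g in groups}


@dataclass
class PipelineConfig:
    """Analysis-side thresholds and file locations for an end-to-end run."""

    counts_path: str
    adjacency_path: str
    out_dir: str
    network_map_path: str | None = None
    r2_min: float = 0.7
    p_max: float = 0.05
    hub_quantile: float = 0.8
    hub_rule: str = "both"  # "both" (conjunctive) or "sum"
    adjust_method: str = "holm"  # or "bh"
    pair_value: str = "r"  # connected-vs-unconnected test value: r|abs_r|signed_r2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.r2_min <= 1.0:
            raise ConfigError("r2_min must lie in [0, 1]")
        if not 0.0 < self.p_max <= 1.0:
            raise ConfigError("p_max must lie in (0, 1]")
        if not 0.0 < self.hub_quantile < 1.0:
            raise ConfigError("hub_quantile must lie in (0, 1)")
        if self.hub_rule not in ("both", "sum"):
            raise ConfigError("hub_rule must be 'both' or 'sum'")
        if self.adjust_method not in ("holm", "bh"):
            raise ConfigError("adjust_method must be 'holm' or 'bh'")
        if self.pair_value not in ("r", "abs_r", "signed_r2"):
            raise ConfigError("pair_value must be r|abs_r|signed_r2")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
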
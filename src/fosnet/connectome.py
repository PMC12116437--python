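"""Correlation-based functional-connectome reconstruction.

Within each experimental group, all pairwise Pearson correlations between
regional c-Fos densities are computed (pairwise-complete observations).  The
signed squared coefficient sign(r)·r² is the working "R²" quantity: the
magnitude is thresholded while the sign survives to color edges.  Candidate
edges are restricted to anatomically connected region pairs (adjacency mask)
and must pass both |R²| > r2_min and p < p_max (strict) to enter the
functional graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationMatrix",
    "correlation_matrix",
    "mask_anatomical",
    "threshold_edges",
    "compare_connected_unconnected",
    "upper_pairs",
]

log = logging.getLogger(__name__)


class ConnectomeError(ValueError):
    pass


@dataclass
class CorrelationMatrix:
    """Group-wise region × region Pearson statistics.

    Masked or undefined entries are NaN in all component matrices.
    """

    r: pd.DataFrame
    signed_r2: pd.DataFrame
    p: pd.DataFrame
    n_pairs: pd.DataFrame
    group: str

    @property
    def regions(self) -> list[str]:
        return list(self.r.index)

    def write(self, directory: str | Path, prefix: str = "") -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name in ("r", "signed_r2", "p", "n_pairs"):
            getattr(self, name).to_csv(d / f"{prefix}{name}.csv")


def correlation_matrix(
    densities: pd.DataFrame | "object", group: str | None = None
) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation over regions.

    Accepts a subject × region DataFrame or a :class:`~fosnet.density.DensityTable`
    (restricted to one group).  Zero-variance regions are flagged and their
    rows/columns left undefined.
    """
    if hasattr(densities, "densities"):  # DensityTable
        if group is None:
            groups = densities.groups
            if len(groups) != 1:
                raise ConnectomeError(
                    "DensityTable spans several groups; restrict or pass group="
                )
            group = groups[0]
            table = densities
        else:
            table = densities.restrict_group(group)
        x = table.densities
    else:
        x = densities
    group = group or ""
    regions = list(x.columns)
    m = len(regions)
    vals = x.to_numpy(dtype=float)

    r = np.full((m, m), np.nan)
    p = np.full((m, m), np.nan)
    n_pairs = np.zeros((m, m), dtype=int)
    sds = np.nanstd(vals, axis=0)
    degenerate = [regions[j] for j in range(m) if sds[j] == 0]
    if degenerate:
        log.warning("zero-variance regions excluded from correlations: %s", degenerate)
    for i in range(m):
        r[i, i] = 1.0
        n_pairs[i, i] = int(np.isfinite(vals[:, i]).sum())
        for j in range(i + 1, m):
            ok = np.isfinite(vals[:, i]) & np.isfinite(vals[:, j])
            n = int(ok.sum())
            n_pairs[i, j] = n_pairs[j, i] = n
            if n < 3 or regions[i] in degenerate or regions[j] in degenerate:
                continue
            xi, xj = vals[ok, i], vals[ok, j]
            if xi.std() == 0 or xj.std() == 0:
                continue
            rij = float(np.corrcoef(xi, xj)[0, 1])
            rij = float(np.clip(rij, -1.0, 1.0))
            # two-sided p from the t transform with n-2 df
            if abs(rij) >= 1.0:
                pij = 0.0
            else:
                t = rij * np.sqrt((n - 2) / (1.0 - rij**2))
                pij = float(2.0 * stats.t.sf(abs(t), df=n - 2))
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij

    idx = pd.Index(regions)
    sr2 = np.sign(r) * r**2
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        signed_r2=pd.DataFrame(sr2, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n_pairs=pd.DataFrame(n_pairs, index=idx, columns=idx),
        group=group,
    )


def _check_adjacency(adj: pd.DataFrame) -> pd.DataFrame:
    a = adj.astype(int)
    if list(a.index) != list(a.columns):
        raise ConnectomeError("adjacency rows/columns carry different labels")
    m = a.to_numpy()
    if np.any(np.diag(m) != 0):
        raise ConnectomeError("adjacency has nonzero diagonal")
    if not np.array_equal(m, m.T):
        # directed source: symmetrize by logical OR (functional graph is undirected)
        a = pd.DataFrame(((m + m.T) > 0).astype(int), index=a.index, columns=a.columns)
    return a


def mask_anatomical(corr: CorrelationMatrix, adj: pd.DataFrame) -> CorrelationMatrix:
    """Set region pairs without anatomical connection to undefined."""
    if set(adj.index) != set(corr.regions):
        only_corr = sorted(set(corr.regions) - set(adj.index))
        only_adj = sorted(set(adj.index) - set(corr.regions))
        raise ConnectomeError(
            f"region label mismatch: correlation-only {only_corr}, "
            f"adjacency-only {only_adj}"
        )
    adj = _check_adjacency(adj).loc[corr.regions, corr.regions]
    keep = adj.to_numpy().astype(bool)
    np.fill_diagonal(keep, True)
    n_masked = int((~keep).sum() // 2)
    log.info("anatomical mask removes %d region pairs for group %s",
             n_masked, corr.group)

    def apply(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        out.values[~keep] = np.nan
        return out

    return CorrelationMatrix(
        r=apply(corr.r),
        signed_r2=apply(corr.signed_r2),
        p=apply(corr.p),
        n_pairs=corr.n_pairs.copy(),
        group=corr.group,
    )


def threshold_edges(
    corr: CorrelationMatrix, r2_min: float = 0.7, p_max: float = 0.05
) -> nx.Graph:
    """Build the functional graph of strong, significant correlations.

    Edge (i, j) exists iff the entry is defined, |sign(r)·r²| > r2_min and
    p < p_max (both strict).  Edges carry sign ('+'/'-'), weight |signed r²|
    and the raw r.
    """
    if not 0.0 <= r2_min <= 1.0 or not 0.0 < p_max <= 1.0:
        raise ConnectomeError("thresholds outside valid ranges")
    g = nx.Graph(group=corr.group, r2_min=r2_min, p_max=p_max)
    g.add_nodes_from(corr.regions)
    sr2 = corr.signed_r2.to_numpy()
    p = corr.p.to_numpy()
    regions = corr.regions
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            v, pij = sr2[i, j], p[i, j]
            if np.isnan(v) or np.isnan(pij):
                continue
            if abs(v) > r2_min and pij < p_max:
                g.add_edge(
                    regions[i],
                    regions[j],
                    sign="+" if v > 0 else "-",
                    weight=float(abs(v)),
                    r=float(corr.r.iat[i, j]),
                )
    return g


def upper_pairs(adj: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of the strict upper triangle of a labeled square matrix."""
    n = len(adj)
    iu, ju = np.triu_indices(n, k=1)
    return iu, ju


def compare_connected_unconnected(
    corr: CorrelationMatrix,
    adj: pd.DataFrame,
    value: str = "r",
    alternative: str = "two-sided",
) -> tuple[float, float, float]:
    """Welch t-test: correlations of anatomically connected vs unconnected pairs.

    Tests whether region pairs with documented axonal connections show higher
    cross-subject correlation than unconnected pairs, over the upper-triangle
    pairs.  Returns (t, Welch df, p).
    """
    if set(adj.index) != set(corr.regions):
        raise ConnectomeError("adjacency labels do not match correlation labels")
    adj = _check_adjacency(adj).loc[corr.regions, corr.regions]
    if value == "r":
        mat = corr.r.to_numpy()
    elif value == "abs_r":
        mat = np.abs(corr.r.to_numpy())
    elif value == "signed_r2":
        mat = corr.signed_r2.to_numpy()
    else:
        raise ConnectomeError(f"unknown pair value {value!r}")
    a = adj.to_numpy().astype(bool)
    iu, ju = upper_pairs(adj)
    vals = mat[iu, ju]
    conn = a[iu, ju]
    ok = np.isfinite(vals)
    x, y = vals[ok & conn], vals[ok & ~conn]
    if len(x) == 0 or len(y) == 0:
        raise ConnectomeError(
            f"empty pair class: {len(x)} connected, {len(y)} unconnected"
        )
    res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    # Welch-Satterthwaite df
    vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
    df = (vx + vy) ** 2 / (vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1))
    return float(res.statistic), float(df), float(res.pvalue)
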
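"""Correlation matrices, anatomical masking, edge thresholding."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fosnet import (
    compare_connected_unconnected,
    correlation_matrix,
    mask_anatomical,
    threshold_edges,
)
from fosnet.connectome import ConnectomeError, CorrelationMatrix


def _density_frame(n=10, regions=("A", "B", "C", "D"), seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.normal(size=(n, len(regions))),
        columns=list(regions),
        index=[f"s{i}" for i in range(n)],
    )


def _full_adj(regions):
    n = len(regions)
    m = np.ones((n, n), dtype=int) - np.eye(n, dtype=int)
    return pd.DataFrame(m, index=list(regions), columns=list(regions))


def _corr_from(sr2, p, regions):
    sr2 = pd.DataFrame(sr2, index=regions, columns=regions, dtype=float)
    p = pd.DataFrame(p, index=regions, columns=regions, dtype=float)
    r = np.sign(sr2) * np.sqrt(sr2.abs())
    n = pd.DataFrame(10, index=regions, columns=regions)
    return CorrelationMatrix(r=r, signed_r2=sr2, p=p, n_pairs=n, group="g")


class TestCorrelationMatrix:
    def test_perfect_linear_dependence(self):
        x = _density_frame()
        x["B"] = 2.0 * x["A"]
        c = correlation_matrix(x)
        assert c.r.loc["A", "B"] == pytest.approx(1.0)
        assert c.signed_r2.loc["A", "B"] == pytest.approx(1.0)

    def test_perfect_anticorrelation_signed(self):
        x = _density_frame()
        x["B"] = -x["A"]
        c = correlation_matrix(x)
        assert c.signed_r2.loc["A", "B"] == pytest.approx(-1.0)

    def test_p_matches_pearsonr(self):
        x = _density_frame(n=12, seed=3)
        c = correlation_matrix(x)
        r_ref, p_ref = stats.pearsonr(x["A"], x["C"])
        assert c.r.loc["A", "C"] == pytest.approx(r_ref)
        assert c.p.loc["A", "C"] == pytest.approx(p_ref)
        assert c.n_pairs.loc["A", "C"] == 12

    def test_pairwise_complete_uses_shared_subjects_only(self):
        x = _density_frame(n=12, seed=4)
        x.loc["s0", "A"] = np.nan
        x.loc["s1", "B"] = np.nan
        c = correlation_matrix(x)
        assert c.n_pairs.loc["A", "B"] == 10
        shared = x.dropna(subset=["A", "B"])
        assert c.r.loc["A", "B"] == pytest.approx(
            stats.pearsonr(shared["A"], shared["B"])[0]
        )

    def test_symmetry_and_bounds(self):
        c = correlation_matrix(_density_frame(n=15, seed=5))
        assert np.allclose(c.r, c.r.T, equal_nan=True)
        assert np.allclose(c.signed_r2.abs(), c.r**2, equal_nan=True)
        assert (c.signed_r2.abs().to_numpy() <= 1.0 + 1e-12).all()

    def test_null_false_positive_rate_near_alpha(self):
        """Independent columns: |r| clears the p<0.05 bar for ~5% of pairs."""
        hits = total = 0
        for seed in range(40):
            c = correlation_matrix(_density_frame(n=10, regions=list("ABCDEFGH"),
                                                  seed=100 + seed))
            iu = np.triu_indices(8, k=1)
            p = c.p.to_numpy()[iu]
            hits += int((p < 0.05).sum())
            total += len(p)
        assert 0.02 < hits / total < 0.09

    def test_zero_variance_region_left_undefined(self):
        x = _density_frame()
        x["B"] = 1.0
        c = correlation_matrix(x)
        assert np.isnan(c.r.loc["A", "B"])
        assert c.r.loc["A", "C"] is not None


class TestMasking:
    def test_all_ones_adjacency_is_identity(self):
        c = correlation_matrix(_density_frame(seed=6))
        m = mask_anatomical(c, _full_adj(c.regions))
        pd.testing.assert_frame_equal(m.signed_r2, c.signed_r2)

    def test_all_zero_adjacency_masks_everything(self):
        c = correlation_matrix(_density_frame(seed=7))
        adj = _full_adj(c.regions) * 0
        m = mask_anatomical(c, adj)
        off = ~np.eye(len(c.regions), dtype=bool)
        assert np.isnan(m.signed_r2.to_numpy()[off]).all()
        assert threshold_edges(m).number_of_edges() == 0

    def test_label_mismatch_reports_difference(self):
        c = correlation_matrix(_density_frame(seed=8))
        adj = _full_adj(["A", "B", "C", "X"])
        with pytest.raises(ConnectomeError, match="X"):
            mask_anatomical(c, adj)

    def test_directed_adjacency_symmetrized_by_or(self):
        c = correlation_matrix(_density_frame(seed=9))
        adj = _full_adj(c.regions) * 0
        adj.loc["A", "B"] = 1  # one direction only
        m = mask_anatomical(c, adj)
        assert not np.isnan(m.r.loc["B", "A"])
        assert np.isnan(m.r.loc["A", "C"])


class TestThresholding:
    regions = ["A", "B", "C"]

    def _simple(self, sr2_ab, p_ab):
        sr2 = np.eye(3)
        p = np.zeros((3, 3)) + 0.5
        sr2[0, 1] = sr2[1, 0] = sr2_ab
        p[0, 1] = p[1, 0] = p_ab
        return _corr_from(sr2, p, self.regions)

    def test_edge_passes_both_criteria(self):
        g = threshold_edges(self._simple(0.71, 0.04))
        assert g.has_edge("A", "B") and g["A"]["B"]["sign"] == "+"

    def test_p_threshold_blocks_strong_correlation(self):
        assert threshold_edges(self._simple(0.90, 0.06)).number_of_edges() == 0

    def test_negative_edge_kept_with_sign(self):
        g = threshold_edges(self._simple(-0.75, 0.01))
        assert g.has_edge("A", "B") and g["A"]["B"]["sign"] == "-"
        assert g["A"]["B"]["weight"] == pytest.approx(0.75)

    def test_thresholds_are_strict(self):
        assert threshold_edges(self._simple(0.70, 0.01)).number_of_edges() == 0
        assert threshold_edges(self._simple(0.71, 0.05)).number_of_edges() == 0

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000),
           r2a=st.floats(0.0, 0.95), r2b=st.floats(0.0, 0.95),
           pa=st.floats(0.001, 0.2), pb=st.floats(0.001, 0.2))
    def test_monotone_thresholding_and_mask_containment(self, seed, r2a, r2b,
                                                        pa, pb):
        rng = np.random.default_rng(seed)
        n = 6
        regions = [f"r{i}" for i in range(n)]
        sr2 = rng.uniform(-1, 1, (n, n))
        sr2 = np.triu(sr2, 1) + np.triu(sr2, 1).T + np.eye(n)
        p = rng.uniform(0, 0.3, (n, n))
        p = np.triu(p, 1) + np.triu(p, 1).T
        corr = _corr_from(sr2, p, regions)
        r2_lo, r2_hi = sorted((r2a, r2b))
        p_lo, p_hi = sorted((pa, pb))
        loose = set(threshold_edges(corr, r2_min=r2_lo, p_max=p_hi).edges)
        tight = set(threshold_edges(corr, r2_min=r2_hi, p_max=p_lo).edges)
        assert tight <= loose

        adj = np.triu(rng.integers(0, 2, (n, n)), 1)
        adj = pd.DataFrame(adj + adj.T, index=regions, columns=regions)
        masked = set(
            threshold_edges(mask_anatomical(corr, adj), r2_min=r2_lo, p_max=p_hi).edges
        )
        assert masked <= loose
        # mask→threshold equals threshold→intersect-with-adjacency
        intersected = {
            (u, v) for (u, v) in loose if adj.loc[u, v] == 1
        }
        assert masked == intersected


class TestConnectedVsUnconnected:
    def test_clear_separation_detected(self):
        rng = np.random.default_rng(0)
        regions = [f"r{i}" for i in range(8)]
        n = 8
        adj = np.triu(rng.integers(0, 2, (n, n)), 1)
        adj = pd.DataFrame(adj + adj.T, index=regions, columns=regions)
        r = np.where(adj.to_numpy() == 1, 0.9, 0.0) + rng.normal(0, 0.01, (n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        corr = CorrelationMatrix(
            r=pd.DataFrame(r, index=regions, columns=regions),
            signed_r2=pd.DataFrame(np.sign(r) * r**2, index=regions, columns=regions),
            p=pd.DataFrame(0.01, index=regions, columns=regions),
            n_pairs=pd.DataFrame(10, index=regions, columns=regions),
            group="g",
        )
        t, df, p = compare_connected_unconnected(corr, adj)
        assert t > 5 and p < 1e-6

    def test_empty_class_rejected(self):
        c = correlation_matrix(_density_frame(seed=10))
        with pytest.raises(ConnectomeError, match="empty"):
            compare_connected_unconnected(c, _full_adj(c.regions) * 0)
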
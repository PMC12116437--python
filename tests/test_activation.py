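"""Activation statistics: NB mixed model, Holm, Cohen's d, Wilcoxon."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fosnet
from fosnet import (
    StudyConfig,
    adjust_pvalues,
    cohens_d,
    fit_network_model,
    fit_region_model,
    generate_study,
    paired_wilcoxon,
)
from fosnet.activation import StatsError, _aggregate_subjects, region_stats_table
from fosnet.nbglmm import fit_nb_mixed


@pytest.fixture(scope="module")
def one_region_counts():
    cfg = StudyConfig.default(seed=11, regions=["VMH"])
    counts, _ = generate_study(cfg)
    return counts


class TestHolm:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ([0.01, 0.02, 0.04], [0.03, 0.04, 0.04]),
            ([0.5], [0.5]),
            ([0.01] * 5, [0.05] * 5),
        ],
    )
    def test_step_down_hand_values(self, raw, expected):
        assert adjust_pvalues(raw, method="holm") == pytest.approx(expected)

    def test_monotone_and_never_below_raw(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(size=40)
        adj = np.asarray(adjust_pvalues(list(raw)))
        assert np.all(adj >= raw)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        assert np.all(adj <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(StatsError):
            adjust_pvalues([0.2, 1.4])

    def test_bh_alternative(self):
        # BH on [0.01, 0.02, 0.04]: [0.03, 0.03, 0.04]
        assert adjust_pvalues([0.01, 0.02, 0.04], method="bh") == pytest.approx(
            [0.03, 0.03, 0.04]
        )


class TestCohensD:
    def test_unit_difference_unit_sd(self):
        a = np.array([0.0, 1.0, 2.0]) + 1.0  # mean 2, sd 1
        b = np.array([0.0, 1.0, 2.0])  # mean 1, sd 1
        assert cohens_d(a, b) == pytest.approx(1.0)

    def test_identical_groups_give_zero(self):
        x = [1.0, 2.0, 3.0]
        assert cohens_d(x, x) == pytest.approx(0.0)

    def test_two_point_hand_value(self):
        assert abs(cohens_d([0.0, 2.0], [1.0, 3.0])) == pytest.approx(
            1.0 / np.sqrt(2.0)
        )

    def test_antisymmetry_and_scale_invariance(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(1, 2, 10), rng.normal(0, 2, 12)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))
        assert cohens_d(5 * a, 5 * b) == pytest.approx(cohens_d(a, b))

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(StatsError, match="pooled"):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestPairedWilcoxon:
    def test_all_zero_differences_degenerate(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        with pytest.raises(StatsError, match="degenerate"):
            paired_wilcoxon(x, x)

    def test_uniform_shift_gives_maximal_rank_statistic(self):
        y = np.arange(10, dtype=float)
        x = y + 1.0
        z, p = paired_wilcoxon(x, y)
        # all 10 signed ranks positive, all |differences| tied at 1:
        # Z = (55 - 27.5) / sqrt(96.25 - (10³-10)/48)
        assert abs(z) == pytest.approx(27.5 / np.sqrt(75.625), rel=1e-6)
        assert p < 0.01

    def test_pair_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0.4, 1, 12), rng.normal(0, 1, 12)
        z1, p1 = paired_wilcoxon(x, y)
        perm = rng.permutation(12)
        z2, p2 = paired_wilcoxon(x[perm], y[perm])
        assert (abs(z1), p1) == pytest.approx((abs(z2), p2))


class TestRegionModel:
    def test_offset_invariance_under_area_rescaling(self, one_region_counts):
        base = fit_region_model(one_region_counts)
        doubled = one_region_counts.copy()
        doubled["area_mm2"] = doubled["area_mm2"] * 2.0
        res = fit_region_model(doubled)
        assert res.chi2 == pytest.approx(base.chi2, abs=2e-3)
        assert res.treatment_lfc_estimate == pytest.approx(
            base.treatment_lfc_estimate, abs=1e-3
        )

    def test_direction_follows_estimate_sign(self, one_region_counts):
        res = fit_region_model(one_region_counts)
        expected = "CTR_higher" if res.treatment_lfc_estimate < 0 else "VPA_higher"
        assert res.direction == expected

    def test_all_zero_group_flagged_degenerate(self, one_region_counts):
        broken = one_region_counts.copy()
        broken.loc[broken["group"] == "VPA", "count"] = 0
        res = fit_region_model(broken)
        assert res.degenerate

    def test_cohens_d_reported_only_in_screening_band(self, counts):
        table = region_stats_table(counts)
        for row in table.itertuples():
            if row.degenerate or not np.isfinite(row.p):
                continue
            in_band = 0.05 < row.p < 0.1
            assert (row.cohens_d is not None and np.isfinite(row.cohens_d)) == in_band
            assert row.p_adjusted >= row.p - 1e-12

    def test_matches_statsmodels_when_no_litter_structure(self):
        """With a single litter the random effect pins at ~0 and the fit must
        agree with a plain NB maximum-likelihood regression."""
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        n = 60
        x = rng.integers(0, 2, n).astype(float)
        X = np.column_stack([np.ones(n), x])
        off = np.log(rng.uniform(0.5, 2.0, n))
        mu = np.exp(1.5 + 0.6 * x + off)
        y = rng.negative_binomial(5.0, 5.0 / (5.0 + mu)).astype(float)
        ours = fit_nb_mixed(y, X, off, np.zeros(n, dtype=int))
        ref = sm.NegativeBinomial(y, X, offset=off).fit(disp=0)
        assert ours.beta == pytest.approx(ref.params[:2], abs=1e-4)
        assert 1.0 / ours.k == pytest.approx(ref.params[-1], rel=1e-2)
        assert ours.loglik == pytest.approx(ref.llf, abs=5e-3)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_glmmTMB_laplace_fit(self, one_region_counts, tmp_path):
        """Independent oracle: glmmTMB (same Laplace approximation) must agree
        on coefficients, dispersion, litter SD and log-likelihood."""
        agg = _aggregate_subjects(one_region_counts)
        csv = tmp_path / "agg.csv"
        agg.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(glmmTMB))
            d <- read.csv('{csv}')
            m <- glmmTMB(count ~ group + (1|litter_id) + offset(log(area)),
                         family = nbinom2, data = d)
            cat(fixef(m)$cond, sigma(m),
                attr(VarCorr(m)$cond$litter_id, 'stddev'),
                as.numeric(logLik(m)), sep='\\n')
        """)
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        b0, b1, k, sigma, ll = map(float, out.stdout.strip().splitlines())

        y = agg["count"].to_numpy(float)
        X = np.column_stack([np.ones(len(y)),
                             (agg["group"] == "VPA").to_numpy(float)])
        off = np.log(agg["area"].to_numpy(float))
        lit = pd.Categorical(agg["litter_id"]).codes
        ours = fit_nb_mixed(y, X, off, lit)
        assert ours.beta == pytest.approx([b0, b1], abs=1e-3)
        assert ours.k == pytest.approx(k, rel=1e-3)
        assert ours.sigma_litter == pytest.approx(sigma, abs=1e-3)
        assert ours.loglik == pytest.approx(ll, abs=1e-3)


class TestNetworkModel:
    def test_single_region_reduces_to_region_model(self, one_region_counts):
        r1 = fit_region_model(one_region_counts)
        r2 = fit_network_model(one_region_counts, include_region_effect=False)
        assert r2.chi2 == pytest.approx(r1.chi2, abs=5e-3)
        assert r2.treatment_lfc_estimate == pytest.approx(
            r1.treatment_lfc_estimate, abs=5e-3
        )

    def test_pooling_beats_single_region_power(self):
        """A uniform effect across a 4-region network: the pooled LR statistic
        should, on average, dominate each single-region statistic."""
        regions = ["A", "B", "C", "D"]
        pooled, single = [], []
        for seed in range(8):
            cfg = StudyConfig.default(
                seed=seed, regions=regions,
                region_area={r: 0.5 for r in regions},
                baseline_log_density={r: 5.0 for r in regions},
                treatment_log_fold_change={r: -0.5 for r in regions},
                slides_per_region={r: 1 for r in regions},
            )
            counts, _ = generate_study(cfg)
            pooled.append(fit_network_model(counts, network="synthetic").chi2)
            single.append(
                max(
                    fit_region_model(counts[counts["region"] == r]).chi2
                    for r in regions[:1]
                )
            )
        assert np.mean(pooled) > np.mean(single)
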
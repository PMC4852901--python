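"""Enrichment factors, classification, binning, breakpoints, and the
statistics used to compare site groups and climate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from paleoprod import trends
from paleoprod.trends import (
    TrendError,
    WindowError,
    bin_5yr,
    classify_sites,
    dbt_enrichment_factor,
    enrichment_factor,
    fit_breakpoint,
    fixture_summary,
    pearson_with_p,
    table1_fixture,
    total_dbt,
    welch_ttest,
    zscores,
)


class TestEnrichmentFactor:
    def test_constant_profile_gives_unity(self):
        years = np.arange(1950, 2012, 3.0)
        r = enrichment_factor(years, np.full_like(years, 1.7))
        assert r.ef == pytest.approx(1.0)

    def test_mean_ratio_of_windows(self):
        years = np.array([1955, 1960, 1965, 1970, 2001, 2003, 2005, 2007, 2009, 2011])
        vals = np.array([1.0] * 4 + [2.0] * 6)
        r = enrichment_factor(years, vals)
        assert r.ef == pytest.approx(2.0)
        assert r.n_modern == 6 and r.n_baseline == 4

    def test_empty_window_raises_naming_window(self):
        years = np.arange(1980.0, 2013.0)  # nothing before 1971
        with pytest.raises(WindowError, match="baseline"):
            enrichment_factor(years, np.ones_like(years))

    def test_interval_count_variants(self):
        years = np.array([1950, 1955, 1960, 1965, 1968, 1975, 2001, 2005, 2009, 2013.0])
        vals = np.array([1, 1, 1, 2, 2, 3, 3, 4, 4, 6.0])
        last2 = enrichment_factor(years, vals, variant="last2")
        # modern = 2 most recent (4, 6); baseline window 1955-1970 → (1, 1, 2, 2)
        assert last2.ef == pytest.approx(5.0 / 1.5)
        pre2 = enrichment_factor(years, vals, variant="pre1970_2")
        # baseline = the 2 intervals immediately before 1970: 1965, 1968
        assert pre2.baseline_window == (1965.0, 1968.0)
        assert pre2.ef == pytest.approx(np.mean([3, 4, 4, 6]) / 2.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100.0))
    def test_scale_invariance(self, scale):
        years = np.arange(1950, 2012, 3.0)
        vals = 1.0 + 0.02 * np.clip(years - 1980, 0, None)
        base = enrichment_factor(years, vals).ef
        scaled = enrichment_factor(years, vals * scale).ef
        assert scaled == pytest.approx(base, rel=1e-9)


class TestDBT:
    def test_total_is_sum_of_parent_and_alkylated(self):
        assert total_dbt(10, 20, 30, 20, 20) == 100
        assert total_dbt(0, 0, 0, 0, 0) == 0

    def test_missing_as_zero_contract(self):
        assert total_dbt(10, 20, np.nan, 20, 20, missing_as_zero=True) == 70

    def test_negative_rejected(self):
        with pytest.raises(TrendError):
            total_dbt(-1, 0, 0, 0, 0)

    def test_step_profile_enrichment(self):
        years = np.arange(1950, 2014, 2.0)
        dbt = np.where(years >= 1970, 140.0, 20.0)
        r = dbt_enrichment_factor(years, dbt)
        # baseline 1955-1970 includes the 1970 interval (140), EF < 7 accordingly
        base = np.mean([20, 20, 20, 20, 20, 20, 20, 140.0])
        assert r.ef == pytest.approx(140.0 / base)

    def test_no_preindustrial_record_is_inapplicable(self):
        years = np.arange(1985, 2014.0)
        assert dbt_enrichment_factor(years, np.full_like(years, 50.0)) is None

    def test_constant_profile_unity(self):
        years = np.arange(1950, 2014, 2.0)
        assert dbt_enrichment_factor(years, np.full_like(years, 9.0)).ef == pytest.approx(1.0)


class TestClassification:
    def test_threshold_rule_and_tie_break(self):
        out = classify_sites({"a": 0.7, "b": 2.1, "c": 2.0, "d": None})
        groups = {c.lake_id: c.group for c in out}
        assert groups == {
            "a": "minimally", "b": "highly", "c": "minimally", "d": "undetermined"
        }

    def test_fixture_rows_classified_as_printed(self):
        df = table1_fixture()
        efs = {r.site: (None if np.isnan(r.dbt_ef) else r.dbt_ef) for r in df.itertuples()}
        groups = {c.lake_id: c.group for c in classify_sites(efs)}
        assert groups["RAMP 271"] == "minimally"  # DBT EF 0.7
        assert groups["NE13"] == "highly"  # DBT EF 2.1
        assert groups["RAMP 227"] == "undetermined"

    def test_fixture_group_counts_match_printed_table(self):
        s = fixture_summary()
        assert (s["n_minimally"], s["n_highly"], s["n_undetermined"]) == (6, 16, 1)
        assert (s["n_breakpoint_minimally"], s["n_breakpoint_highly"]) == (5, 13)

    def test_fixture_group_difference_not_significant(self):
        """Chl-a enrichment does not differ between DBT groups (Welch p > 0.05)."""
        assert fixture_summary()["welch_p"] > 0.05


class TestZscores:
    def test_simple_sequence(self):
        np.testing.assert_allclose(zscores(np.array([1.0, 2.0, 3.0])), [-1, 0, 1])

    def test_normalization_identity(self, rng):
        x = rng.normal(5, 3, 40)
        z = zscores(x)
        assert abs(z.mean()) < 1e-12 and z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a=st.floats(0.1, 50.0), b=st.floats(-100.0, 100.0))
    def test_affine_invariance(self, a, b):
        x = np.linspace(0.5, 4.0, 20) ** 2
        np.testing.assert_allclose(zscores(a * x + b), zscores(x), atol=1e-8)

    def test_zero_sd_rejected(self):
        with pytest.raises(TrendError):
            zscores(np.full(5, 2.0))


class TestBinning:
    def test_calendar_anchored_bins(self):
        out = bin_5yr(np.array([1971.0, 1973.0]), np.array([1.0, 3.0]))
        assert out.bin_start.tolist() == [1970]
        assert out["mean"].iloc[0] == pytest.approx(2.0)

    def test_single_observation(self):
        out = bin_5yr(np.array([1988.0]), np.array([7.0]))
        assert out["mean"].iloc[0] == 7.0 and out["n"].iloc[0] == 1

    def test_empty_input(self):
        assert len(bin_5yr(np.array([]), np.array([]))) == 0

    def test_group_mean_matches_bruteforce_loop(self, rng):
        years = rng.uniform(1950, 2014, 200)
        vals = rng.normal(size=200)
        out = bin_5yr(years, vals)
        for row in out.itertuples():
            mask = (years >= row.bin_start) & (years <= row.bin_start + 4.999999)
            in_bin = np.floor(years / 5) * 5 == row.bin_start
            assert row.n == in_bin.sum()
            assert row.mean == pytest.approx(vals[in_bin].mean(), rel=1e-12)
            assert mask.sum() == in_bin.sum()


class TestBreakpoint:
    def test_noiseless_two_segment_recovered_exactly(self):
        years = np.arange(1950, 2011, 2.0)
        vals = np.where(years <= 1970, 1.0, 1.0 + 0.1 * (years - 1970))
        bp = fit_breakpoint(years, vals)
        assert bp.tau == pytest.approx(1970.0, abs=1e-4)
        assert bp.slope_pre == pytest.approx(0.0, abs=1e-10)
        assert bp.slope_post == pytest.approx(0.1, rel=1e-6)
        assert bp.rss_model == pytest.approx(0.0, abs=1e-18)
        assert bp.p_value < 1e-10

    def test_pure_line_degenerates_to_equal_slopes(self):
        years = np.arange(1950, 2011, 2.0)
        vals = 0.5 + 0.01 * (years - 1950)
        bp = fit_breakpoint(years, vals)
        assert bp.slope_pre == pytest.approx(bp.slope_post, abs=1e-8)
        # incremental fit over a single line is negligible
        line_rss = 0.0
        assert bp.rss_model <= line_rss + 1e-16

    def test_grid_stage_matches_bruteforce_scan(self, rng):
        """The candidate-τ profile search equals an independent exhaustive scan."""
        for _ in range(5):
            years = np.sort(rng.uniform(1950, 2012, 30))
            vals = rng.normal(size=30)
            bp = fit_breakpoint(years, vals, min_edge=3)
            best_rss, best_tau = np.inf, None
            for tau in years[(np.arange(30) >= 2) & (np.arange(30) < 27)]:
                n_left = (years <= tau).sum()
                if n_left < 3 or (30 - n_left) < 3:
                    continue
                X = np.column_stack(
                    [np.ones(30), years, np.clip(years - tau, 0, None)]
                )
                beta, *_ = np.linalg.lstsq(X, vals, rcond=None)
                rss = float(np.sum((vals - X @ beta) ** 2))
                if rss < best_rss - 1e-12:
                    best_rss, best_tau = rss, tau
            assert bp.rss_model <= best_rss + 1e-9

    def test_rss_nesting(self, rng):
        years = np.sort(rng.uniform(1950, 2012, 25))
        vals = rng.normal(size=25)
        bp = fit_breakpoint(years, vals)
        X = np.column_stack([np.ones(25), years])
        beta, *_ = np.linalg.lstsq(X, vals, rcond=None)
        line_rss = float(np.sum((vals - X @ beta) ** 2))
        assert bp.rss_model <= line_rss + 1e-9 <= bp.rss_null + 1e-9

    def test_caller_supplied_inapplicability(self):
        bp = fit_breakpoint(
            np.arange(20.0), np.arange(20.0), applicable=False, reason="no stable baseline"
        )
        assert not bp.applicable and bp.reason == "no stable baseline"

    def test_too_few_points_inapplicable(self):
        bp = fit_breakpoint(np.arange(5.0), np.ones(5))
        assert not bp.applicable

    def test_stochastic_recovery_within_2se(self, rng):
        """|τ̂ − τ| ≤ 2·SE(τ̂) in ≥90% of simulations at a clearly detectable
        effect (8 noise-SD per decade; the default simulated chl-a histories
        carry far stronger signals still)."""
        hits = []
        for _ in range(200):
            t = np.arange(1952, 2012, 2.0)
            y = 1.0 + 0.04 * np.clip(t - 1980.0, 0, None) + rng.standard_normal(len(t)) * 0.05
            bp = fit_breakpoint(t, y)
            hits.append(abs(bp.tau - 1980.0) <= 2 * bp.tau_se)
        assert np.mean(hits) >= 0.90


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_ttest(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        """a={1,2,3}, b={1,2,3,4,5}: t = −1/√(1/3+1/2), Welch df ≈ 5.88."""
        t, df, p = welch_ttest(np.array([1.0, 2, 3]), np.array([1.0, 2, 3, 4, 5]))
        assert t == pytest.approx(-1.0954451, abs=1e-6)
        assert df == pytest.approx(5.882353, abs=1e-4)

    def test_matches_scipy_oracle(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.4, 2, 17)
        t, df, p = welch_ttest(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_agrees_with_permutation_oracle(self, rng):
        """Under near-null data the Welch p matches a label-permutation p."""
        a, b = rng.normal(0, 1, 25), rng.normal(0.3, 1, 30)
        t_obs, _, p_welch = welch_ttest(a, b)
        pooled = np.concatenate([a, b])
        count = 0
        n_perm = 20_000
        prng = np.random.default_rng(99)
        for _ in range(n_perm):
            perm = prng.permutation(pooled)
            pa, pb = perm[:25], perm[25:]
            t_p = (pa.mean() - pb.mean()) / np.sqrt(pa.var(ddof=1) / 25 + pb.var(ddof=1) / 30)
            count += abs(t_p) >= abs(t_obs)
        p_perm = count / n_perm
        assert p_perm == pytest.approx(p_welch, abs=0.05)

    def test_zero_variance_equal_means_convention(self):
        t, df, p = welch_ttest(np.full(3, 2.0), np.full(4, 2.0))
        assert t == 0.0 and p == 1.0


class TestPearson:
    def test_perfect_linear_relationships(self):
        x = np.arange(10.0)
        r, p, n = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and p == pytest.approx(0.0, abs=1e-12)
        r2, _, _ = pearson_with_p(x, -x)
        assert r2 == pytest.approx(-1.0)

    def test_matches_covariance_formula_and_scipy(self, rng):
        x, y = rng.normal(size=8), rng.normal(size=8)
        r, p, n = pearson_with_p(x, y)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        r_direct = cov / (x.std() * y.std())
        assert r == pytest.approx(r_direct, abs=1e-12)
        ref_r, ref_p = stats.pearsonr(x, y)
        assert r == pytest.approx(ref_r, abs=1e-12)
        assert p == pytest.approx(ref_p, abs=1e-10)

    def test_constant_series_rejected(self):
        with pytest.raises(TrendError):
            pearson_with_p(np.ones(5), np.arange(5.0))


class TestFixtureSummary:
    def test_mean_chla_ef_rounds_to_printed_average(self):
        s = fixture_summary()
        assert round(s["chla_ef_mean"], 1) == 1.8
        assert (s["chla_ef_min"], s["chla_ef_max"]) == (1.1, 5.3)
        assert (s["dbt_ef_min"], s["dbt_ef_max"]) == (0.7, 37.4)
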
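"""Chi-square tests, FDR, group comparisons, log-scale correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tedynamics import (
    DegenerateInputError,
    ExemplarDB,
    ExemplarRecord,
    LibraryCounts,
    SiRNALibrary,
    SimulationConfig,
    bh_fdr,
    chi2_corr,
    chi2_prop,
    chi2_std,
    compare_abundance,
    correlation_log,
    generate_exemplar_db,
    group_compare,
    simulate_genomic_hits,
)
from tedynamics import test_proportionality as proportionality_table


class TestChi2Std:
    def test_hand_computed_statistic(self):
        assert chi2_std(10, 990, 20, 980).statistic == pytest.approx(3.384, abs=5e-4)

    def test_exact_null_is_zero(self):
        assert chi2_std(10, 990, 20, 1980).statistic == pytest.approx(0.0, abs=1e-12)

    def test_equals_squared_two_proportion_z(self):
        """The 1-df chi-square is identically the squared Z statistic."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 500, size=4)
            stat = chi2_std(a, b, c, d).statistic
            n1, n2 = a + b, c + d
            p1, p2 = a / n1, c / n2
            pooled = (a + c) / (n1 + n2)
            z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
            assert stat == pytest.approx(z**2, abs=1e-9, rel=1e-9)

    def test_zero_margin_untestable(self):
        assert not chi2_std(0, 10, 0, 20).testable


class TestChi2Corr:
    def test_hand_computed_statistic(self):
        out = chi2_corr(30, 10, 5.0, 5.0)
        assert out.statistic == pytest.approx(10.0)

    def test_counts_proportional_to_coverage_give_zero(self):
        assert chi2_corr(20, 10, 2.0, 1.0).statistic == pytest.approx(0.0, abs=1e-12)

    def test_equal_coverage_equals_binomial_half_statistic(self):
        """With equal coverages the statistic is (n_a - T/2)^2 / (T/4) exactly."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            n_a, n_b = rng.integers(1, 1000, size=2)
            t = n_a + n_b
            expected = (n_a - t / 2) ** 2 / (t / 4)
            assert chi2_corr(n_a, n_b, 3.3, 3.3).statistic == pytest.approx(expected)

    def test_p_matches_exact_binomial_in_decision_region(self):
        """Normal-approximation p within 0.01 of the exact binomial test.

        Agreement is checked where the test makes decisions (exact p <=
        0.05) with expected counts >= 20; for central p-values the binomial
        point mass alone exceeds 0.01, so no continuity-free approximation
        can match there.
        """
        rng = np.random.default_rng(2)
        checked = 0
        for _ in range(2000):
            f_a, f_b = rng.uniform(0.5, 2.0, size=2)
            p = f_a / (f_a + f_b)
            t = int(rng.integers(80, 400))
            n_a = int(rng.binomial(t, p))
            if min(t * p, t * (1 - p)) < 20 or n_a in (0, t):
                continue
            exact = sps.binomtest(n_a, t, p).pvalue
            if exact > 0.05:
                continue
            approx = chi2_corr(n_a, t - n_a, f_a, f_b).p_value
            assert abs(approx - exact) < 0.01
            checked += 1
        assert checked > 30

    def test_type_i_error_calibrated_under_coverage_imbalance(self):
        """Null rejection rate at alpha=0.05 within (0.04, 0.06), 1e4 exemplars."""
        rng = np.random.default_rng(3)
        m = 10_000
        f_a, f_b = 2.0, 1.0  # 2x coverage imbalance
        p = f_a / (f_a + f_b)
        t = rng.integers(150, 600, size=m)  # expected counts >= 50
        n_a = rng.binomial(t, p)
        stat = (n_a - t * p) ** 2 / (t * p * (1 - p))
        rate = (sps.chi2.sf(stat, 1) < 0.05).mean()
        assert 0.04 < rate < 0.06

    def test_degenerate_proportion_rejected(self):
        with pytest.raises(DegenerateInputError):
            chi2_corr(1, 2, 0.0, 1.0)


class TestChi2Prop:
    def test_identical_counts_and_coverages_zero(self):
        assert chi2_prop(50, 50, 80, 80, 1, 1, 1, 1).statistic == 0.0

    def test_hand_computed_statistic(self):
        out = chi2_prop(100, 100, 400, 100, 1, 1, 1, 1)
        assert out.statistic == pytest.approx(np.log(4.0) ** 2 / 0.0325)
        assert out.statistic == pytest.approx(59.1, abs=0.05)

    def test_zero_count_untestable_not_error(self):
        assert not chi2_prop(0, 10, 5, 5, 1, 1, 1, 1).testable

    def test_coverage_shift_absorbed(self):
        """Doubling one library's coverages with doubled counts stays null."""
        base = chi2_prop(100, 100, 100, 100, 1, 1, 1, 1).statistic
        shifted = chi2_prop(200, 100, 200, 100, 2, 1, 2, 1).statistic
        assert base == pytest.approx(0.0, abs=1e-12)
        assert shifted == pytest.approx(0.0, abs=1e-12)

    def test_calibration_under_simulated_proportional_null(self):
        """Rejection rate at alpha=0.05 in (0.035, 0.065) with counts >= 50."""
        rng = np.random.default_rng(4)
        m = 10_000
        lam_n = rng.uniform(100, 500, size=m)
        n_a = rng.poisson(lam_n)
        n_b = rng.poisson(lam_n)
        lam_s = 2.0 * lam_n  # siRNA expectation proportional to copies
        s_a = rng.poisson(lam_s)
        s_b = rng.poisson(lam_s)
        ok = np.minimum.reduce([n_a, n_b, s_a, s_b]) >= 1
        r = np.log(n_a[ok] / n_b[ok])
        stat = (np.log(s_a[ok] / s_b[ok]) - r) ** 2 / (
            1 / s_a[ok] + 1 / s_b[ok] + 1 / n_a[ok] + 1 / n_b[ok]
        )
        rate = (sps.chi2.sf(stat, 1) < 0.05).mean()
        assert 0.035 < rate < 0.065

    def test_power_monotone_in_deviation(self):
        """Rejection rate grows as siRNA departs from proportionality."""
        rng = np.random.default_rng(5)
        m = 2_000
        rates = []
        for dev in (1.0, 1.5, 2.0):
            n_a = rng.poisson(200, size=m)
            n_b = rng.poisson(200, size=m)
            s_a = rng.poisson(400 * dev, size=m)
            s_b = rng.poisson(400, size=m)
            ok = np.minimum.reduce([n_a, n_b, s_a, s_b]) >= 1
            r = np.log(n_a[ok] / n_b[ok])
            stat = (np.log(s_a[ok] / s_b[ok]) - r) ** 2 / (
                1 / s_a[ok] + 1 / s_b[ok] + 1 / n_a[ok] + 1 / n_b[ok]
            )
            rates.append((sps.chi2.sf(stat, 1) < 0.05).mean())
        assert rates[0] < rates[1] < rates[2]

    def test_binomial_variant_matches_delta_roughly(self):
        d = chi2_prop(100, 100, 400, 100, 1, 1, 1, 1, variant="delta")
        b = chi2_prop(100, 100, 400, 100, 1, 1, 1, 1, variant="binomial")
        assert b.statistic > 30  # both variants reject decisively
        assert d.statistic > 30


class TestBH:
    def test_hand_computed_qvalues(self):
        out = bh_fdr([0.001, 0.02, 0.9], q_threshold=0.01)
        assert out["q_value"].tolist() == pytest.approx([0.003, 0.03, 0.9])
        assert out["significant"].tolist() == [True, False, False]

    def test_all_ones(self):
        out = bh_fdr([1.0, 1.0, 1.0])
        assert (out["q_value"] == 1.0).all()
        assert not out["significant"].any()

    def test_step_up_monotonicity(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=100)
        out = bh_fdr(p)
        df = out.sort_values("p_value")
        assert (df["q_value"].diff().dropna() >= -1e-15).all()

    def test_nan_excluded_from_family(self):
        out = bh_fdr([0.01, np.nan, 0.04])
        # m = 2: q = (0.02, nan, 0.04)
        assert out["q_value"].iloc[0] == pytest.approx(0.02)
        assert np.isnan(out["q_value"].iloc[1])
        assert out["q_value"].iloc[2] == pytest.approx(0.04)

    def test_empty_input(self):
        assert bh_fdr([]).empty


class TestGroupCompare:
    def test_null_groups_share_a_letter(self):
        rng = np.random.default_rng(7)
        values = pd.Series(rng.normal(size=150))
        groups = pd.Series(["D"] * 50 + ["R1"] * 50 + ["R2"] * 50, index=values.index)
        comp = group_compare(values, groups)
        letters = set(comp.letters.values())
        assert len(letters) == 1  # all share one letter

    def test_separated_groups_get_distinct_letters(self):
        rng = np.random.default_rng(8)
        values = pd.Series(
            np.concatenate(
                [rng.normal(0, 0.1, 50), rng.normal(5, 0.1, 50), rng.normal(10, 0.1, 50)]
            )
        )
        groups = pd.Series(["D"] * 50 + ["R1"] * 50 + ["R2"] * 50, index=values.index)
        comp = group_compare(values, groups)
        assert comp.kw_p_value < 1e-10
        assert len({comp.letters[g] for g in ("D", "R1", "R2")}) == 3

    def test_constant_variable_gives_zero_statistic(self):
        values = pd.Series(np.ones(60))
        groups = pd.Series(["D"] * 20 + ["R1"] * 20 + ["R2"] * 20, index=values.index)
        comp = group_compare(values, groups)
        assert comp.kw_statistic == 0.0

    def test_single_group_rejected(self):
        values = pd.Series(np.arange(10.0))
        groups = pd.Series(["D"] * 10, index=values.index)
        with pytest.raises(DegenerateInputError):
            group_compare(values, groups)


class TestCorrelationLog:
    def test_identity(self):
        hits = pd.Series([1.0, 10.0, 100.0, 1000.0])
        out = correlation_log(hits, hits)
        assert out.r_squared == pytest.approx(1.0)
        assert out.slope == pytest.approx(1.0)
        assert out.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_factor_moves_intercept(self):
        hits = pd.Series([1.0, 10.0, 100.0, 1000.0])
        out = correlation_log(hits, 2.0 * hits)
        assert out.slope == pytest.approx(1.0)
        assert out.intercept == pytest.approx(np.log(2.0))

    def test_zero_hits_excluded(self):
        a = pd.Series([0.0, 1.0, 10.0, 100.0, 1000.0])
        b = pd.Series([5.0, 1.0, 10.0, 100.0, 0.0])
        assert correlation_log(a, b).n == 3

    def test_replicate_libraries_highly_correlated(self):
        """Two libraries simulated from one truth give r^2 > 0.95."""
        cfg = SimulationConfig(seed=31, n_dna=100, n_r1=80, n_r2=50, library_size=1_000_000)
        db, truth = generate_exemplar_db(cfg)
        cfg2 = SimulationConfig(seed=32, n_dna=100, n_r1=80, n_r2=50, library_size=1_000_000)
        a = simulate_genomic_hits(db, truth, cfg, "B73")
        b = simulate_genomic_hits(db, truth, cfg2, "B73")
        out = correlation_log(a.hit_series(db), b.hit_series(db))
        assert out.r_squared > 0.95

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateInputError):
            correlation_log(pd.Series([1.0, 2.0]), pd.Series([1.0, 2.0]))


class TestTableRunners:
    @pytest.fixture()
    def db2(self):
        return ExemplarDB(
            [
                ExemplarRecord("teA", "DNA", "DTA", 1000),
                ExemplarRecord("teB", "RNA", "RLC", 1000),
                ExemplarRecord("teC", "RNA", "RLG", 1000),
            ]
        )

    def test_compare_abundance_matches_scalar(self, db2):
        a = LibraryCounts("A", {"teA": 30.0, "teB": 70.0, "teC": 0.0}, fgs_hits=10.0)
        b = LibraryCounts("B", {"teA": 10.0, "teB": 90.0, "teC": 0.0}, fgs_hits=10.0)
        table = compare_abundance(a, b, db2, test="corr")
        assert table.loc["teA", "statistic"] == pytest.approx(
            chi2_corr(30, 10, 10, 10).statistic
        )
        assert not table.loc["teC", "testable"]
        table_std = compare_abundance(a, b, db2, test="std")
        assert table_std.loc["teA", "statistic"] == pytest.approx(
            chi2_std(30, 70, 10, 90).statistic
        )

    def test_proportionality_runner_matches_scalar(self, db2):
        a = LibraryCounts("A", {"teA": 100.0, "teB": 50.0, "teC": 1.0}, fgs_hits=5.0)
        b = LibraryCounts("B", {"teA": 100.0, "teB": 50.0, "teC": 0.0}, fgs_hits=5.0)
        sa = SiRNALibrary("A", 24, {"teA": 400.0, "teB": 20.0, "teC": 3.0})
        sb = SiRNALibrary("B", 24, {"teA": 100.0, "teB": 20.0, "teC": 3.0})
        table = proportionality_table(a, b, sa, sb, db2)
        expected = chi2_prop(
            100, 100, 400, 100, 5, 5, sa.total_sirna_hits, sb.total_sirna_hits
        ).statistic
        assert table.loc["teA", "statistic"] == pytest.approx(expected)
        assert not table.loc["teC", "testable"]
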
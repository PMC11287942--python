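"""Bland-Altman agreement, paired tests, correlations, family selection."""

import numpy as np
import pandas as pd
import pytest

from dietval.compare import (PairedSeries, bland_altman, choose_family,
                             paired_correlation, paired_location_test,
                             summarize_validation)

import _oracles


def series(a, b, name="x") -> PairedSeries:
    return PairedSeries(name, "", np.asarray(a, float), np.asarray(b, float))


class TestBlandAltman:
    def test_identical_series(self, rng):
        a = rng.normal(10, 2, 12)
        ba = bland_altman(series(a, a.copy()))
        assert ba.mean_diff == 0.0
        assert ba.loa_lower == ba.loa_upper == 0.0
        assert ba.slope == pytest.approx(0.0, abs=1e-12)

    def test_hand_arithmetic(self):
        ba = bland_altman(series([1.0, 2.0, 3.0], [0.0, 0.0, 0.0]))
        assert ba.mean_diff == pytest.approx(2.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert (ba.loa_lower, ba.loa_upper) == (pytest.approx(0.0), pytest.approx(4.0))
        assert ba.loa_half_width == pytest.approx(2 * ba.sd_diff)

    def test_all_fields_match_formula_oracle(self, rng):
        a = rng.normal(10000, 2000, 10)
        b = rng.normal(10200, 1200, 10)
        ba = bland_altman(series(a, b), reference="series_b")
        exp = _oracles.bland_altman_fields(a, b)
        for field in ("mean_diff", "sd_diff", "loa_lower", "loa_upper",
                      "loa_half_width", "slope", "intercept", "r", "p"):
            assert getattr(ba, field) == pytest.approx(exp[field], rel=1e-10), field
        assert ba.mean_diff_pct == pytest.approx(100 * exp["mean_diff"] / b.mean())

    def test_antisymmetric_under_swap(self, rng):
        s = series(rng.normal(5, 1, 15), rng.normal(6, 2, 15))
        fwd, rev = bland_altman(s), bland_altman(s.swapped())
        assert fwd.mean_diff == pytest.approx(-rev.mean_diff, rel=1e-12)
        assert fwd.sd_diff == pytest.approx(rev.sd_diff, rel=1e-12)

    def test_loa_uses_two_sd_exactly(self, rng):
        s = series(rng.normal(0, 1, 30), rng.normal(0, 1, 30))
        ba = bland_altman(s)
        assert ba.loa_upper - ba.loa_lower == pytest.approx(4 * ba.sd_diff, rel=1e-12)

    def test_degenerate_averages_report_missing_regression(self):
        ba = bland_altman(series([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]))  # all avgs = 2
        assert np.isnan(ba.slope) and np.isnan(ba.p)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(series([1.0, 2.0], [0.0, 0.0]))

    def test_loa_coverage_property(self, rng):
        """~95.4% of normal differences fall inside the +/-2 SD limits."""
        covs = []
        for _ in range(100):
            d = rng.normal(0, 1, 52)
            s = series(d, np.zeros(52))
            ba = bland_altman(s)
            covs.append(np.mean((d >= ba.loa_lower) & (d <= ba.loa_upper)))
        assert abs(np.mean(covs) - 0.954) < 0.01


class TestPairedLocation:
    def test_symmetric_differences_give_t_zero_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0] * 3)
        b = a + np.array([-1.0, 1.0] * 6)
        stat, p = paired_location_test(series(a, b), "t")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_pure_shift_detected(self, rng):
        a = rng.normal(10, 2, 20)
        stat, p = paired_location_test(series(a, a + 5.0), "t")
        assert p < 1e-10

    def test_t_matches_closed_form_oracle(self, rng):
        for _ in range(10):
            a, b = rng.normal(10, 2, 15), rng.normal(11, 2, 15)
            stat, p = paired_location_test(series(a, b), "t")
            t_exp, p_exp = _oracles.paired_t(a, b)
            assert stat == pytest.approx(t_exp, rel=1e-10)
            assert p == pytest.approx(p_exp, rel=1e-10)

    def test_wilcoxon_exact_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            a, b = rng.normal(10, 2, 12), rng.normal(11, 2, 12)
            stat, p = paired_location_test(series(a, b), "wilcoxon")
            stat_exp, p_exp = _oracles.wilcoxon_signed_rank(a - b, "exact")
            assert stat == pytest.approx(stat_exp)
            assert p == pytest.approx(p_exp, rel=1e-10)

    def test_wilcoxon_large_n_matches_normal_approximation(self, rng):
        a, b = rng.normal(10, 2, 40), rng.normal(10.8, 2, 40)
        stat, p = paired_location_test(series(a, b), "wilcoxon")
        _, p_exp = _oracles.wilcoxon_signed_rank(a - b, "approx")
        assert p == pytest.approx(p_exp, rel=1e-10)

    def test_all_zero_differences_convention(self):
        a = np.ones(6)
        stat, p = paired_location_test(series(a, a), "wilcoxon")
        assert p == 1.0

    def test_wilcoxon_needs_five_nonzero(self):
        a = np.array([1.0, 1.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([1.0, 1.0, 1.0, 2.5, 3.5, 4.5, 5.5])
        with pytest.raises(ValueError):
            paired_location_test(series(a, b), "wilcoxon")


class TestCorrelation:
    def test_affine_map_gives_pearson_one(self, rng):
        a = rng.normal(0, 1, 20)
        r, p = paired_correlation(series(a, 2 * a + 1), "pearson")
        assert r == pytest.approx(1.0)

    def test_monotone_nonlinearity(self, rng):
        a = np.abs(rng.normal(2, 0.5, 25))
        r_s, _ = paired_correlation(series(a, a**2), "spearman")
        r_p, _ = paired_correlation(series(a, a**2), "pearson")
        assert r_s == pytest.approx(1.0)
        assert r_p < 1.0

    def test_matches_sigma_formula_oracles(self, rng):
        for _ in range(10):
            a, b = rng.normal(0, 1, 18), rng.normal(0, 1, 18)
            r, p = paired_correlation(series(a, b), "pearson")
            r_exp, p_exp = _oracles.pearson_with_p(a, b)
            assert (r, p) == (pytest.approx(r_exp, rel=1e-10),
                              pytest.approx(p_exp, rel=1e-10))
            r, p = paired_correlation(series(a, b), "spearman")
            r_exp, p_exp = _oracles.spearman_with_p(a, b)
            assert (r, p) == (pytest.approx(r_exp, rel=1e-10),
                              pytest.approx(p_exp, rel=1e-10))

    def test_pearson_invariant_under_affine_rescaling(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        r1, _ = paired_correlation(series(a, b), "pearson")
        r2, _ = paired_correlation(series(3 * a + 7, b), "pearson")
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_spearman_invariant_under_monotone_transform(self, rng):
        a, b = rng.normal(2, 0.3, 20), rng.normal(2, 0.3, 20)
        r1, _ = paired_correlation(series(a, b), "spearman")
        r2, _ = paired_correlation(series(np.exp(a), b), "spearman")
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_zero_variance_gives_missing(self):
        r, p = paired_correlation(series(np.ones(5), [1.0, 2.0, 3.0, 4.0, 5.0]),
                                  "pearson")
        assert np.isnan(r) and np.isnan(p)


class TestChooseFamily:
    def test_normal_differences_choose_parametric(self):
        hits = 0
        for seed in range(100):
            d = np.random.default_rng(seed).normal(0, 1, 50)
            hits += choose_family(d) == "parametric"
        assert hits >= 90

    def test_heavy_tailed_differences_choose_nonparametric(self):
        hits = 0
        for seed in range(100):
            d = np.random.default_rng(seed).lognormal(0, 1, 50)
            hits += choose_family(d) == "nonparametric"
        assert hits >= 90


class TestSummarize:
    @staticmethod
    def _cohorts(rng, n=20):
        pid = [f"p{i}" for i in range(n)]
        a = pd.DataFrame({"participant_id": pid, "x": rng.normal(10, 2, n),
                          "y": rng.lognormal(1, 0.5, n)})
        b = pd.DataFrame({"participant_id": pid, "x": rng.normal(10, 2, n),
                          "y": rng.lognormal(1, 0.5, n)})
        return a, b

    def test_self_comparison(self, rng):
        a, _ = self._cohorts(rng)
        table, plots = summarize_validation(a, a.copy(), ["x", "y"])
        assert (table.mean_diff == 0).all()
        assert np.allclose(table.r, 1.0)
        assert set(plots) == {"x", "y"}
        assert (plots["x"].difference == 0).all()

    def test_each_variable_appears_exactly_once(self, rng):
        a, b = self._cohorts(rng)
        table, _ = summarize_validation(a, b, ["x", "y"])
        assert list(table.variable) == ["x", "y"]

    def test_family_override_honoured(self, rng):
        a, b = self._cohorts(rng)
        table, _ = summarize_validation(a, b, ["x"],
                                        family_overrides={"x": "nonparametric"})
        assert table.loc[0, "location_test"] == "wilcoxon"
        assert table.loc[0, "correlation"] == "spearman"

    def test_unmatched_participants_dropped(self, rng):
        a, b = self._cohorts(rng)
        table, _ = summarize_validation(a.iloc[:15], b.iloc[5:], ["x"])
        assert table.loc[0, "n"] == 10
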
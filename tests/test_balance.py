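"""Balance diagnostics: standardized differences, % bias, circular
Wheeler-Watson statistic, and the eight-covariate report."""

import numpy as np
import pandas as pd
import pytest

from admatch.balance import (balance_report, day_of_year_to_angle, percent_bias,
                             standardized_difference, wheeler_watson)
from admatch.matching import MatchSet

from conftest import tiny_design


class TestStandardizedDifference:
    def test_identical_samples_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert standardized_difference(x, x) == 0.0

    def test_binary_proportions_influenza_row(self):
        # 12.8% vs 0.9% prevalence: delta ~ 0.483 under the two-proportion form
        t = np.r_[np.ones(128), np.zeros(872)]
        c = np.r_[np.ones(9), np.zeros(991)]
        assert standardized_difference(t, c, binary=True) == pytest.approx(0.483, abs=0.02)

    def test_translation_invariance(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=50), rng.normal(1.0, 2.0, size=60)
        d1 = standardized_difference(a, b)
        d2 = standardized_difference(a + 7.5, b + 7.5)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_zero_variance_flagged_not_thrown(self):
        assert np.isnan(standardized_difference([1.0, 1.0], [2.0, 2.0]))
        assert standardized_difference([1.0, 1.0], [1.0, 1.0]) == 0.0


class TestPercentBias:
    @pytest.mark.parametrize("pre, post, expected", [
        (0.483, 0.315, 34.8),
        (0.914, 0.013, 98.6),
        (0.456, 0.014, 96.9),
    ])
    def test_printed_rows(self, pre, post, expected):
        assert percent_bias(pre, post) == pytest.approx(expected, abs=0.05)

    def test_no_improvement_is_zero(self):
        for x in (0.1, 0.5, 2.0):
            assert percent_bias(x, x) == 0.0

    def test_nonpositive_pre_flagged(self):
        assert np.isnan(percent_bias(0.0, 0.1))


class TestWheelerWatson:
    def test_symmetric_four_point_instance_is_zero(self):
        a = np.array([np.pi / 2, 3 * np.pi / 2])
        b = np.array([np.pi, 2 * np.pi])
        assert wheeler_watson(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 2 * np.pi, 40)
        b = rng.uniform(0, 2 * np.pi, 55)
        w0 = wheeler_watson(a, b)
        shift = 1.234
        w1 = wheeler_watson((a + shift) % (2 * np.pi), (b + shift) % (2 * np.pi))
        assert w1 == pytest.approx(w0, abs=1e-9)

    def test_separation_grows_with_n(self):
        rng = np.random.default_rng(2)
        stats = []
        for n in (50, 200, 800):
            winter = rng.vonmises(0.0, 2.0, n)
            summer = rng.vonmises(np.pi, 2.0, n)
            stats.append(wheeler_watson(winter % (2 * np.pi), summer % (2 * np.pi)))
        assert stats[0] < stats[1] < stats[2]

    def test_identical_angles_degenerate(self):
        assert np.isnan(wheeler_watson([1.0, 1.0], [1.0]))

    def test_weights_equal_explicit_replication(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 2 * np.pi, 30)
        b = rng.uniform(0, 2 * np.pi, 10)
        k = np.array([1, 3, 2, 1, 1, 4, 1, 2, 1, 1])
        w_weighted = wheeler_watson(a, b, weights_b=k)
        w_explicit = wheeler_watson(a, np.repeat(b, k))
        assert w_weighted == pytest.approx(w_explicit, rel=1e-12)


class TestDayOfYearAngle:
    def test_wraparound_and_antipode(self):
        assert day_of_year_to_angle(365, 365) == pytest.approx(2 * np.pi)
        assert day_of_year_to_angle(183, 366) == pytest.approx(np.pi)

    def test_circular_distance_across_new_year(self):
        dec31 = day_of_year_to_angle(365, 365)
        jan1 = day_of_year_to_angle(1, 365)
        d = np.abs(dec31 - jan1)
        circ = min(d, 2 * np.pi - d)
        assert circ == pytest.approx(2 * np.pi / 365)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="day of year"):
            day_of_year_to_angle(0, 365)


class TestBalanceReport:
    def test_self_matching_gives_zero_post_differences(self):
        # duplicate the treated block as artificial controls; each treated
        # day matched to its own copy
        t = tiny_design(n_treated=20, n_control=0, seed=4).iloc[:20].assign(w=1)
        c = t.copy()
        c["w"] = 0
        design = pd.concat([t, c], ignore_index=True)
        design["date"] = pd.date_range("2003-01-04", periods=len(design))
        pairs = pd.DataFrame({"treated_id": np.arange(20),
                              "control_id": np.arange(20, 40),
                              "distance": 0.0})
        match = MatchSet(pairs, {20 + i: 1 for i in range(20)})
        scores = np.tile(np.linspace(0.3, 0.7, 20), 2)
        rep = balance_report(design, scores, match)
        linear = rep.table[rep.table["covariate"] != "day_of_year"]
        np.testing.assert_allclose(linear["delta_post"].to_numpy(float), 0.0, atol=1e-12)

    def test_panel_has_eight_rows_and_sizes(self, milan_run):
        _, _, est = milan_run
        rep = est.balance_
        assert len(rep.table) == 8
        assert rep.n_controls_effective == rep.n_treated
        assert rep.n_controls_used <= rep.n_controls

    def test_matching_improves_balance_on_confounded_series(self, milan_run):
        _, _, est = milan_run
        tab = est.balance_.table.set_index("covariate")
        for cov in ("propensity", "temp03"):
            assert tab.loc[cov, "delta_post"] < tab.loc[cov, "delta_pre"]
        doy = tab.loc["day_of_year"]
        assert doy["w_post"] < doy["w_pre"]

    def test_weighted_means_match_explicit_replication(self, milan_run):
        _, _, est = milan_run
        design, match = est.design_, est.match_
        m_ids = np.array(sorted(match.K))
        k = np.array([match.K[i] for i in m_ids])
        x = design["temp03"].to_numpy()
        weighted = np.average(x[m_ids], weights=k)
        explicit = x[np.repeat(m_ids, k)].mean()
        assert weighted == pytest.approx(explicit, rel=1e-12)
        row = est.balance_.table.set_index("covariate").loc["temp03"]
        assert row["mean_matched"] == pytest.approx(explicit, rel=1e-12)
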
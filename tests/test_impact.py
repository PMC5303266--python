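"""Impact estimation: day-level differences, additivity, the
Abadie-Imbens variance, confidence intervals and the sensitivity analysis."""

import numpy as np
import pandas as pd
import pytest

from admatch.impact import (ai_variance, confidence_interval, day_level_ad,
                            sensitivity_exclude, total_ad)
from admatch.matching import MatchSet
from admatch.strata import AGES, CAUSES, DEATH_COLUMNS

from conftest import tiny_design


def _match_for(design, mapping):
    pairs = pd.DataFrame({
        "treated_id": list(mapping),
        "control_id": list(mapping.values()),
        "distance": 0.0,
    })
    K = pairs["control_id"].value_counts().to_dict()
    return MatchSet(pairs, {int(k): int(v) for k, v in K.items()})


def _scores(design):
    rng = np.random.default_rng(99)
    w = design["w"].to_numpy()
    return np.where(w == 1, rng.uniform(0.6, 0.9, len(design)),
                    rng.uniform(0.1, 0.4, len(design)))


class TestDayLevelAD:
    @pytest.mark.parametrize("obs, ctrl, expected", [(35, 31, 4), (28, 30, -2), (7, 7, 0)])
    def test_examples(self, obs, ctrl, expected):
        assert day_level_ad(obs, ctrl) == expected


class TestTotalAD:
    def test_equal_counts_give_zero(self):
        design = tiny_design(n_treated=3, n_control=6, seed=1)
        for col in DEATH_COLUMNS:
            design[col] = 4
        match = _match_for(design, {0: 3, 1: 4, 2: 5})
        est = total_ad(design, match, _scores(design))
        assert est.ad == 0
        assert (est.ad_by_day["ad_i"] == 0).all()
        assert est.variance == 0.0

    def test_known_pair_differences(self):
        design = tiny_design(n_treated=3, n_control=6, seed=2)
        for col in DEATH_COLUMNS:
            design[col] = 0
        # put the whole signal in one stratum: observed totals differ by 4, -2, 1
        design.loc[[0, 1, 2], "deaths_cvd_75p"] = [10, 5, 8]
        design.loc[[3, 4, 5], "deaths_cvd_75p"] = [6, 7, 7]
        match = _match_for(design, {0: 3, 1: 4, 2: 5})
        est = total_ad(design, match, _scores(design))
        assert list(est.ad_by_day["ad_i"]) == [4, -2, 1]
        assert est.ad == 3

    def test_additivity_across_strata_and_margins(self, milan_run):
        _, _, est = milan_run
        total = est.estimate().ad
        by_cause = [est.estimate(cause=c).ad for c in CAUSES]
        by_age = [est.estimate(age=a).ad for a in AGES]
        cells = [est.estimate(cause=c, age=a).ad for c in CAUSES for a in AGES]
        assert sum(by_cause) == total
        assert sum(by_age) == total
        assert sum(cells) == total
        assert isinstance(total, int)

    def test_ci_brackets_point(self, milan_run):
        _, _, est = milan_run
        imp = est.estimate()
        assert imp.ci[0] <= imp.ad <= imp.ci[1]

    def test_unmatched_treated_rejected(self):
        design = tiny_design()
        match = _match_for(design, {0: 3})
        match.unmatched.append(1)
        with pytest.raises(ValueError, match="unmatched"):
            total_ad(design, match, _scores(design))


class TestAIVariance:
    def test_constant_outcomes_give_zero_variance(self):
        design = tiny_design(n_treated=4, n_control=5, seed=3)
        for col in DEATH_COLUMNS:
            design[col] = 2
        match = _match_for(design, {0: 4, 1: 5, 2: 6, 3: 7})
        assert ai_variance(design, match, _scores(design)) == 0.0

    def test_hand_computed_two_group_instance(self):
        # 2 treated, 2 controls; J=1 neighbors are the other member of each
        # group; sigma2_i = (1/2)(y_i - y_other)^2; coefficients are 1 for the
        # treated and -K for the used control (K=1 and 0 here).
        design = tiny_design(n_treated=2, n_control=2, seed=4)
        for col in DEATH_COLUMNS:
            design[col] = 0
        y = np.array([9.0, 5.0, 3.0, 6.0])
        design["deaths_cvd_75p"] = y
        scores = np.array([0.8, 0.7, 0.3, 0.2])
        match = _match_for(design, {0: 2, 1: 2})
        sigma2 = 0.5 * np.array([
            (y[0] - y[1]) ** 2, (y[1] - y[0]) ** 2,
            (y[2] - y[3]) ** 2, (y[3] - y[2]) ** 2,
        ])
        coef = np.array([1.0, 1.0, -2.0, 0.0])
        expected = float((coef ** 2 * sigma2).sum())
        got = ai_variance(design, match, scores)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_relabeling_invariance(self):
        design = tiny_design(n_treated=3, n_control=5, seed=5)
        scores = _scores(design)
        match = _match_for(design, {0: 3, 1: 3, 2: 7})
        v1 = ai_variance(design, match, scores)
        # reverse the day order, remapping ids
        n = len(design)
        perm = np.arange(n)[::-1]
        design2 = design.iloc[perm].reset_index(drop=True)
        remap = {old: n - 1 - old for old in range(n)}
        match2 = _match_for(design2, {remap[t]: remap[c] for t, c in
                                      zip(match.pairs["treated_id"],
                                          match.pairs["control_id"])})
        v2 = ai_variance(design2, match2, scores[perm])
        assert v1 == pytest.approx(v2, rel=1e-12)

    def test_nonnegative_and_group_size_guard(self, milan_run):
        _, _, est = milan_run
        v = ai_variance(est.design_, est.match_, est.propensity_model_.propensity_)
        assert v >= 0.0
        with pytest.raises(ValueError, match="J"):
            ai_variance(est.design_, est.match_, est.propensity_model_.propensity_,
                        J=10 ** 6)

    def test_heterogeneity_variant_positive(self, milan_run):
        _, _, est = milan_run
        v = ai_variance(est.design_, est.match_, est.propensity_model_.propensity_,
                        heterogeneity=True)
        assert v > 0.0


class TestConfidenceInterval:
    def test_zero_variance_degenerate(self):
        assert confidence_interval(5.0, 0.0) == (5.0, 5.0)

    def test_standard_normal_quantile(self):
        lo, hi = confidence_interval(0.0, 1.0, level=0.90)
        assert lo == pytest.approx(-1.645, abs=5e-4)
        assert hi == pytest.approx(1.645, abs=5e-4)

    def test_nesting_in_level(self):
        lo90, hi90 = confidence_interval(10.0, 4.0, level=0.90)
        lo95, hi95 = confidence_interval(10.0, 4.0, level=0.95)
        assert lo95 < lo90 and hi95 > hi90

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            confidence_interval(0.0, -1.0)
        with pytest.raises(ValueError):
            confidence_interval(0.0, 1.0, level=1.5)


class TestSensitivity:
    def test_all_zero_flag_identical_to_total(self, milan_run):
        _, _, est = milan_run
        full = est.estimate()
        excl = sensitivity_exclude(est.design_, est.match_,
                                   est.propensity_model_.propensity_,
                                   exclude_flag=np.zeros(len(est.design_), dtype=int))
        assert excl.ad == full.ad
        assert excl.n_treated == full.n_treated
        assert excl.variance == pytest.approx(full.variance)

    def test_excluding_largest_contributions_lowers_total(self, milan_run):
        _, _, est = milan_run
        full = est.estimate()
        ad_i = full.ad_by_day.set_index("treated_id")["ad_i"]
        top = ad_i.nlargest(50).index
        flag = np.zeros(len(est.design_), dtype=int)
        flag[np.asarray(top)] = 1
        excl = sensitivity_exclude(est.design_, est.match_,
                                   est.propensity_model_.propensity_, exclude_flag=flag)
        assert excl.ad < full.ad
        assert excl.n_treated == full.n_treated - 50

    def test_influenza_exclusion_reduces_confounding(self):
        """When influenza inflates mortality and coincides with treated days,
        the flu-excluded estimate tracks the flu-free subset's true AD better
        than the full-sample estimate does."""
        from admatch import AttributableDeathsEstimator
        from admatch.simulate import generate_series, milan_like_config
        err_excl, err_full = [], []
        for seed in range(5):
            cfg = milan_like_config(seed=seed).replace(influenza_treated_log_rr=0.5)
            series, truth = generate_series(cfg)
            est = AttributableDeathsEstimator().fit(series)
            flu = est.design_["influenza"].to_numpy()
            t_ids = est.match_.pairs["treated_id"].to_numpy()
            keep = t_ids[flu[t_ids] == 0]
            # subset truth: true AD over retained treated days
            tab = truth.table.iloc[3:].reset_index(drop=True)
            y1 = tab.filter(like="y1_").to_numpy().sum(axis=1)
            y0 = tab.filter(like="y0_").to_numpy().sum(axis=1)
            sub_truth = (y1[keep] - y0[keep]).sum()
            excl = est.sensitivity()
            full = est.estimate()
            err_excl.append(abs(excl.ad - sub_truth))
            err_full.append(abs(full.ad - sub_truth))
        assert np.mean(err_excl) < np.mean(err_full)

    def test_empty_retained_subset_rejected(self, milan_run):
        _, _, est = milan_run
        with pytest.raises(ValueError):
            sensitivity_exclude(est.design_, est.match_,
                                est.propensity_model_.propensity_,
                                exclude_flag=np.ones(len(est.design_), dtype=int))
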
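"""Covariate balance diagnostics before and after matching.

Balance is assessed descriptively: absolute standardized mean differences
and the percentage bias reduction achieved by matching for linear
covariates, and the two-sample Wheeler-Watson uniform-scores statistic for
the circular covariate "day of year".  Matched-control statistics weight
each control day by its reuse count K, so they describe the matched sample
actually used to impute counterfactual outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .matching import MatchSet

__all__ = [
    "standardized_difference",
    "percent_bias",
    "wheeler_watson",
    "day_of_year_to_angle",
    "balance_report",
    "BalanceReport",
]

#: covariates checked by the standard balance panel
BALANCE_PANEL = ("propensity", "temp03", "humidity", "weekend", "day_of_year",
                 "influenza", "heat", "warm_season")


def standardized_difference(x_treated, x_other, binary: bool = False) -> float:
    """Absolute standardized mean difference between two samples.

    ``|m_t - m_o| / sqrt((v_t + v_o)/2)`` with ``v`` the sample variances,
    replaced by ``p(1-p)`` for binary covariates.  Returns NaN (an
    undefined-balance flag, not an error) when the pooled variance is zero.
    """
    xt = np.asarray(x_treated, dtype=float)
    xo = np.asarray(x_other, dtype=float)
    if xt.size == 0 or xo.size == 0:
        raise ValueError("both groups must be nonempty")
    mt, mo = xt.mean(), xo.mean()
    if binary:
        vt, vo = mt * (1.0 - mt), mo * (1.0 - mo)
    else:
        vt = xt.var(ddof=1) if xt.size > 1 else 0.0
        vo = xo.var(ddof=1) if xo.size > 1 else 0.0
    pooled = 0.5 * (vt + vo)
    if pooled <= 0:
        return 0.0 if mt == mo else np.nan
    return abs(mt - mo) / np.sqrt(pooled)


def _weighted_standardized_difference(xt, xo, w_o, binary: bool = False) -> float:
    """Standardized difference with weighted 'other' group (reuse counts)."""
    xt = np.asarray(xt, dtype=float)
    xo = np.asarray(xo, dtype=float)
    w = np.asarray(w_o, dtype=float)
    mt, mo = xt.mean(), np.average(xo, weights=w)
    if binary:
        vt, vo = mt * (1.0 - mt), mo * (1.0 - mo)
    else:
        vt = xt.var(ddof=1) if xt.size > 1 else 0.0
        vo = np.average((xo - mo) ** 2, weights=w)
        n_eff = w.sum()
        vo = vo * n_eff / (n_eff - 1.0) if n_eff > 1 else vo
    pooled = 0.5 * (vt + vo)
    if pooled <= 0:
        return 0.0 if mt == mo else np.nan
    return abs(mt - mo) / np.sqrt(pooled)


def percent_bias(delta_pre: float, delta_post: float) -> float:
    """Percentage reduction of the standardized difference by matching."""
    if not delta_pre > 0:
        return np.nan
    return 100.0 * (delta_pre - delta_post) / delta_pre


def day_of_year_to_angle(day, year_length) -> np.ndarray:
    """Map day-of-year (1..year_length) to an angle in (0, 2*pi]."""
    day = np.asarray(day, dtype=float)
    year_length = np.asarray(year_length, dtype=float)
    if np.any((day < 1) | (day > year_length)):
        raise ValueError("day of year must lie in [1, year_length]")
    return 2.0 * np.pi * day / year_length


def wheeler_watson(angles_a, angles_b, weights_b=None) -> float:
    """Two-sample Wheeler-Watson uniform-scores statistic.

    The pooled angles are replaced by uniform scores 2*pi*rank/n (mid-ranks
    for ties); with C_g, S_g the within-group resultant components of the
    scores, W = 2 * sum_g (C_g^2 + S_g^2) / n_g.  W >= 0, and larger values
    indicate a larger discrepancy between the two circular distributions;
    under random labelling W is asymptotically chi-square with 2 df.

    ``weights_b`` (reuse counts) replicates group-b members when the second
    sample is a matched-control multiset.
    """
    a = np.asarray(angles_a, dtype=float)
    b = np.asarray(angles_b, dtype=float)
    if weights_b is not None:
        b = np.repeat(b, np.asarray(weights_b, dtype=int))
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return np.nan  # all angles identical: statistic degenerate
    ranks = rankdata(pooled, method="average")
    beta = 2.0 * np.pi * ranks / pooled.size
    w_stat = 0.0
    for g, n_g in ((beta[: a.size], a.size), (beta[a.size:], b.size)):
        w_stat += (np.cos(g).sum() ** 2 + np.sin(g).sum() ** 2) / n_g
    return 2.0 * w_stat


def _warm_season(dates: pd.Series) -> np.ndarray:
    """Warm-season indicator: May 1 through September 30."""
    month = pd.to_datetime(dates).dt.month.to_numpy()
    return ((month >= 5) & (month <= 9)).astype(float)


@dataclass
class BalanceReport:
    """Balance panel (one row per covariate) plus group sizes."""

    table: pd.DataFrame
    n_treated: int
    n_controls: int
    n_controls_used: int
    n_controls_effective: int


def balance_report(design: pd.DataFrame, fit, match: MatchSet) -> BalanceReport:
    """Assemble the standard eight-covariate balance panel.

    ``fit`` may be a fitted :class:`PropensityScoreModel`, a
    ``PropensityFit`` or a raw score vector.  Linear covariates get
    pre/post standardized differences and % bias; day-of-year gets the
    Wheeler-Watson statistic pre/post and its % reduction.  Matched-control
    columns weight controls by their reuse counts; ``n_controls_used`` and
    ``n_controls_effective`` report both sizes of the matched control group.
    """
    scores = getattr(fit, "propensity_", None)
    if scores is None:
        scores = getattr(fit, "scores", fit)
    scores = np.asarray(scores, dtype=float)

    w = design["w"].to_numpy(int)
    t_idx = np.flatnonzero(w == 1)
    c_idx = np.flatnonzero(w == 0)
    m_ids = np.array(sorted(match.K), dtype=int)
    m_w = np.array([match.K[i] for i in m_ids], dtype=float)

    values = {
        "propensity": (scores, False),
        "temp03": (design["temp03"].to_numpy(float), False),
        "humidity": (design["humidity"].to_numpy(float), False),
        "weekend": (design["weekend"].to_numpy(float), True),
        "influenza": (design["influenza"].to_numpy(float), True),
        "heat": (design["heat"].to_numpy(float), True),
        "warm_season": (_warm_season(design["date"]), True),
    }

    rows = []
    for name in BALANCE_PANEL:
        if name == "day_of_year":
            ang = day_of_year_to_angle(design["day_of_year"].to_numpy(),
                                       design["year_length"].to_numpy())
            w_pre = wheeler_watson(ang[t_idx], ang[c_idx])
            w_post = wheeler_watson(ang[t_idx], ang[m_ids], weights_b=m_w)
            rows.append({
                "covariate": name, "mean_treated": np.nan,
                "mean_controls": np.nan, "mean_matched": np.nan,
                "delta_pre": np.nan, "delta_post": np.nan, "pct_bias": np.nan,
                "w_pre": w_pre, "w_post": w_post,
                "pct_reduction": percent_bias(w_pre, w_post),
            })
            continue
        x, binary = values[name]
        d_pre = standardized_difference(x[t_idx], x[c_idx], binary=binary)
        d_post = _weighted_standardized_difference(x[t_idx], x[m_ids], m_w, binary=binary)
        rows.append({
            "covariate": name,
            "mean_treated": x[t_idx].mean(),
            "mean_controls": x[c_idx].mean(),
            "mean_matched": np.average(x[m_ids], weights=m_w),
            "delta_pre": d_pre, "delta_post": d_post,
            "pct_bias": percent_bias(d_pre, d_post),
            "w_pre": np.nan, "w_post": np.nan, "pct_reduction": np.nan,
        })

    return BalanceReport(
        table=pd.DataFrame(rows),
        n_treated=int(t_idx.size),
        n_controls=int(c_idx.size),
        n_controls_used=match.n_controls_used,
        n_controls_effective=int(sum(match.K.values())),
    )
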
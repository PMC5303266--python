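"""Attributable-deaths estimation from matched pairs.

For each treated day the missing low-exposure potential outcome is imputed
by the death count of its matched control day; the day-level attributable
deaths are the difference of the two counts and the total is their sum over
treated days (the SATT on the count scale).  Because a single match set
drives every cause x age stratum, the total is exactly additive across
strata and margins.

The variance follows the Abadie-Imbens matching estimator: writing the total
as sum_i (W_i - (1-W_i) K_i) Y_i with K_i the control reuse counts,

    Var = sum_i (W_i - (1-W_i) K_i)^2 * sigma2_i,

where sigma2_i = J/(J+1) * (Y_i - mean of the J nearest same-group
neighbors)^2 estimates the day-level conditional outcome variance from
propensity-score nearest neighbors within the same treatment group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .matching import MatchSet
from .strata import select_death_columns

__all__ = [
    "ImpactEstimate",
    "day_level_ad",
    "total_ad",
    "ai_variance",
    "confidence_interval",
    "sensitivity_exclude",
    "impact_table",
]


@dataclass
class ImpactEstimate:
    """Total attributable deaths for one stratum selection, with 90% CI."""

    ad: int
    variance: float
    ci: tuple[float, float]
    n_treated: int
    level: float
    cause: str | None = None
    age: str | None = None
    ad_by_day: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    @property
    def satt(self) -> float:
        """Per-treated-day average effect (AD / N1)."""
        return self.ad / self.n_treated


def day_level_ad(y_obs: int, y_matched_control: int) -> int:
    """Difference between an observed treated count and its imputed
    counterfactual; negative values are legitimate imputation noise."""
    return int(y_obs) - int(y_matched_control)


def _stratum_outcome(design: pd.DataFrame, cause: str | None, age: str | None) -> np.ndarray:
    cols = select_death_columns(cause, age)
    missing = [c for c in cols if c not in design.columns]
    if missing:
        raise ValueError(f"design table lacks outcome columns: {missing}")
    return design[cols].to_numpy(float).sum(axis=1)


def _coefficients(n: int, treated_ids: np.ndarray, match: MatchSet) -> np.ndarray:
    """Per-day weights of the total-AD linear form: W_i - (1-W_i) K_i."""
    coef = np.zeros(n)
    coef[treated_ids] = 1.0
    for cid, k in match.K.items():
        coef[cid] = -float(k)
    return coef


def _nn_conditional_variance(y: np.ndarray, scores: np.ndarray, w: np.ndarray,
                             J: int) -> np.ndarray:
    """sigma2_i from the J nearest same-treatment-group neighbors in score."""
    sigma2 = np.zeros(y.size)
    for grp in (0, 1):
        idx = np.flatnonzero(w == grp)
        if idx.size < J + 1:
            raise ValueError(
                f"group {grp} has {idx.size} days; J={J} needs at least {J + 1}"
            )
        s = scores[idx]
        order = np.argsort(s, kind="stable")
        idx_sorted, s_sorted = idx[order], s[order]
        m = idx.size
        for pos in range(m):
            lo, hi = pos, pos  # grow a window of J neighbors around pos
            picked = []
            for _ in range(J):
                left_d = s_sorted[pos] - s_sorted[lo - 1] if lo > 0 else np.inf
                right_d = s_sorted[hi + 1] - s_sorted[pos] if hi + 1 < m else np.inf
                # ties toward the earlier day id for determinism
                if left_d < right_d or (
                    left_d == right_d and lo > 0 and hi + 1 < m
                    and idx_sorted[lo - 1] < idx_sorted[hi + 1]
                ):
                    lo -= 1
                    picked.append(idx_sorted[lo])
                else:
                    hi += 1
                    picked.append(idx_sorted[hi])
            ybar = y[np.array(picked)].mean()
            sigma2[idx_sorted[pos]] = (J / (J + 1.0)) * (y[idx_sorted[pos]] - ybar) ** 2
    return sigma2


def ai_variance(design: pd.DataFrame, match: MatchSet, scores: np.ndarray,
                cause: str | None = None, age: str | None = None, J: int = 1,
                heterogeneity: bool = False) -> float:
    """Abadie-Imbens variance of the total-AD estimator (deaths squared).

    The default is the conditional-variance form above.  With
    ``heterogeneity=True`` the effect-heterogeneity variant is used instead:
    the across-pairs dispersion of the day-level effects plus the
    reused-control correction,

        Var = sum_{W=1} (AD_i - AD/N1)^2 + sum_{W=0} K_i (K_i - 1) sigma2_i.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    y = _stratum_outcome(design, cause, age)
    w = np.zeros(len(design), dtype=int)
    t_ids = match.pairs["treated_id"].to_numpy()
    w[design["w"].to_numpy(int) == 1] = 1
    scores = np.asarray(scores, dtype=float)

    if heterogeneity:
        c_ids = match.pairs["control_id"].to_numpy()
        ad_i = y[t_ids] - y[c_ids]
        tau = ad_i.mean()
        sigma2 = _nn_conditional_variance(y, scores, w, J)
        k = np.array(list(match.K.values()), dtype=float)
        cids = np.array(list(match.K), dtype=int)
        return float(((ad_i - tau) ** 2).sum() + (k * (k - 1.0) * sigma2[cids]).sum())

    coef = _coefficients(len(design), t_ids, match)
    sigma2 = _nn_conditional_variance(y, scores, w, J)
    return float((coef ** 2 * sigma2).sum())


def confidence_interval(ad: float, var: float, level: float = 0.90) -> tuple[float, float]:
    """Normal-approximation CI on the count scale."""
    if var < 0:
        raise ValueError("variance must be >= 0")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    z = norm.ppf(0.5 * (1.0 + level))
    half = z * np.sqrt(var)
    return float(ad - half), float(ad + half)


def total_ad(design: pd.DataFrame, match: MatchSet, scores: np.ndarray,
             cause: str | None = None, age: str | None = None,
             level: float = 0.90, J: int = 1,
             heterogeneity: bool = False) -> ImpactEstimate:
    """Total attributable deaths for a (possibly marginal) stratum.

    ``cause=None`` / ``age=None`` sum over that margin; both ``None`` gives
    the all-natural-causes, all-ages total.  The same match set is used for
    every stratum, so totals are exactly additive across strata.
    """
    if match.unmatched:
        raise ValueError(f"{len(match.unmatched)} treated days are unmatched")
    y = _stratum_outcome(design, cause, age)
    t_ids = match.pairs["treated_id"].to_numpy()
    c_ids = match.pairs["control_id"].to_numpy()
    ad_i = (y[t_ids] - y[c_ids]).astype(int)
    ad = int(ad_i.sum())
    var = ai_variance(design, match, scores, cause=cause, age=age, J=J,
                      heterogeneity=heterogeneity)
    by_day = pd.DataFrame({
        "treated_id": t_ids, "control_id": c_ids, "ad_i": ad_i,
    })
    if "date" in design.columns:
        by_day.insert(0, "date", design["date"].to_numpy()[t_ids])
    return ImpactEstimate(
        ad=ad, variance=var, ci=confidence_interval(ad, var, level),
        n_treated=len(t_ids), level=level, cause=cause, age=age, ad_by_day=by_day,
    )


def sensitivity_exclude(design: pd.DataFrame, match: MatchSet, scores: np.ndarray,
                        exclude_flag: str | np.ndarray = "influenza",
                        cause: str | None = None, age: str | None = None,
                        level: float = 0.90, J: int = 1,
                        heterogeneity: bool = False) -> ImpactEstimate:
    """Recompute the impact over treated days with the exclusion flag off.

    The original propensity fit and matches are kept; flagged treated days
    are simply dropped from the summation (and the reuse counts K are
    recomputed for the retained pairs).
    """
    flag = design[exclude_flag].to_numpy() if isinstance(exclude_flag, str) \
        else np.asarray(exclude_flag)
    if flag.shape[0] != len(design):
        raise ValueError("exclusion flag must be defined for every day")
    t_ids = match.pairs["treated_id"].to_numpy()
    keep = t_ids[flag[t_ids] == 0]
    if keep.size == 0:
        raise ValueError("exclusion removes every treated day")
    sub = match.subset(keep)
    return total_ad(design, sub, scores, cause=cause, age=age, level=level,
                    J=J, heterogeneity=heterogeneity)


def impact_table(design: pd.DataFrame, match: MatchSet, scores: np.ndarray,
                 level: float = 0.90, J: int = 1,
                 heterogeneity: bool = False) -> pd.DataFrame:
    """Cause x age impact grid including margins (the headline results table).

    Rows: the three natural-cause groups plus the all-natural margin;
    columns: AD and CI per age class plus the all-ages margin.
    """
    from .strata import AGES, CAUSES

    rows = []
    for cause in (*CAUSES, None):
        row: dict[str, object] = {"cause": cause or "all_natural"}
        for age in (*AGES, None):
            est = total_ad(design, match, scores, cause=cause, age=age,
                           level=level, J=J, heterogeneity=heterogeneity)
            label = age or "all_ages"
            row[f"ad_{label}"] = est.ad
            row[f"ci_low_{label}"] = round(est.ci[0], 1)
            row[f"ci_high_{label}"] = round(est.ci[1], 1)
        rows.append(row)
    return pd.DataFrame(rows)
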
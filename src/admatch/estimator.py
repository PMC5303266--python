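"""End-to-end estimator: daily series in, attributable deaths out.

Orchestrates the design phase (design table, propensity model, matching,
balance diagnostics -- none of which reads the outcome columns) strictly
before the analysis phase (impact estimation on the matched pairs).
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator

from .balance import BalanceReport, balance_report
from .design import make_design
from .impact import ImpactEstimate, impact_table, sensitivity_exclude, total_ad
from .matching import NearestNeighborMatcher, reuse_histogram
from .propensity import PropensityScoreModel

__all__ = ["AttributableDeathsEstimator"]


class AttributableDeathsEstimator(BaseEstimator):
    """Propensity-score-matching estimator of attributable deaths.

    Parameters
    ----------
    threshold : exposure threshold (ug/m3) defining treated days on the
        lag 0-1 mean; the boundary is inclusive.
    calendar_spline_df_per_year, tensor_marginal_dims : propensity-basis
        dimensions (see :class:`~admatch.propensity.PropensityScoreModel`).
    caliper : optional maximum score distance for a valid match.
    match_on : "score" (raw probability scale) or "logit".
    j_neighbors : J in the Abadie-Imbens conditional-variance estimator.
    ci_level : confidence level of the reported intervals.
    heterogeneity : use the effect-heterogeneity variance variant.

    Fitted attributes: ``design_``, ``propensity_model_``, ``match_``,
    ``balance_``, ``impact_`` (all-natural total), ``impact_table_``.
    """

    def __init__(self, threshold: float = 40.0,
                 calendar_spline_df_per_year: int = 5,
                 tensor_marginal_dims: tuple[int, int] = (5, 3),
                 caliper: float | None = None, match_on: str = "score",
                 j_neighbors: int = 1, ci_level: float = 0.90,
                 heterogeneity: bool = False):
        self.threshold = threshold
        self.calendar_spline_df_per_year = calendar_spline_df_per_year
        self.tensor_marginal_dims = tensor_marginal_dims
        self.caliper = caliper
        self.match_on = match_on
        self.j_neighbors = j_neighbors
        self.ci_level = ci_level
        self.heterogeneity = heterogeneity

    # -- design phase: no outcome data involved ------------------------------

    def fit(self, series: pd.DataFrame, y=None) -> "AttributableDeathsEstimator":
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must lie in (0, 1)")
        self.design_ = make_design(series, threshold=self.threshold)
        self.propensity_model_ = PropensityScoreModel(
            calendar_spline_df_per_year=self.calendar_spline_df_per_year,
            tensor_marginal_dims=self.tensor_marginal_dims,
        ).fit(self.design_)
        matcher = NearestNeighborMatcher(caliper=self.caliper, on=self.match_on)
        matcher.fit(self.propensity_model_.propensity_, self.design_["w"].to_numpy())
        self.matcher_ = matcher
        self.match_ = matcher.match_set_
        self.balance_ = balance_report(self.design_, self.propensity_model_, self.match_)
        return self

    # -- analysis phase -------------------------------------------------------

    def estimate(self, cause: str | None = None, age: str | None = None) -> ImpactEstimate:
        return total_ad(self.design_, self.match_,
                        self.propensity_model_.propensity_, cause=cause, age=age,
                        level=self.ci_level, J=self.j_neighbors,
                        heterogeneity=self.heterogeneity)

    def sensitivity(self, exclude_flag: str = "influenza",
                    cause: str | None = None, age: str | None = None) -> ImpactEstimate:
        return sensitivity_exclude(self.design_, self.match_,
                                   self.propensity_model_.propensity_,
                                   exclude_flag=exclude_flag, cause=cause, age=age,
                                   level=self.ci_level, J=self.j_neighbors,
                                   heterogeneity=self.heterogeneity)

    @property
    def impact_(self) -> ImpactEstimate:
        return self.estimate()

    @property
    def impact_table_(self) -> pd.DataFrame:
        return impact_table(self.design_, self.match_,
                            self.propensity_model_.propensity_,
                            level=self.ci_level, J=self.j_neighbors,
                            heterogeneity=self.heterogeneity)

    def reuse_histogram_(self) -> pd.DataFrame:
        n_controls = int((self.design_["w"] == 0).sum())
        return reuse_histogram(self.match_, n_controls)

    def balance_table_(self) -> BalanceReport:
        return self.balance_
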
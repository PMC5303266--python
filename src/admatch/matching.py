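"""1:1 nearest-neighbor matching with replacement on the propensity score.

Matching is a design-phase operation: it sees day identifiers and scores
only, never outcomes.  Each treated day is paired with the control day whose
score is closest; controls may be reused, and the reuse counts K feed the
variance of the impact estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = ["MatchSet", "NearestNeighborMatcher", "nn_match", "reuse_histogram"]


@dataclass
class MatchSet:
    """Treated-to-control pairs and control reuse counts.

    ``pairs`` has one row per treated day: (treated_id, control_id,
    distance).  ``K`` maps each used control id to its reuse count; controls
    never used do not appear.  ``unmatched`` lists treated ids excluded by a
    caliper (empty in the default, caliper-free procedure).
    """

    pairs: pd.DataFrame
    K: dict[int, int]
    unmatched: list[int] = field(default_factory=list)

    @property
    def n_treated(self) -> int:
        return len(self.pairs)

    @property
    def n_controls_used(self) -> int:
        return len(self.K)

    def control_of(self) -> dict[int, int]:
        return dict(zip(self.pairs["treated_id"], self.pairs["control_id"]))

    def subset(self, treated_ids) -> "MatchSet":
        """Restrict to a subset of treated days, recomputing reuse counts."""
        keep = self.pairs[self.pairs["treated_id"].isin(set(treated_ids))]
        if keep.empty:
            raise ValueError("subset leaves no treated days")
        K = keep["control_id"].value_counts().to_dict()
        return MatchSet(keep.reset_index(drop=True), {int(k): int(v) for k, v in K.items()})


def nn_match(scores_treated: dict[int, float], scores_control: dict[int, float],
             caliper: float | None = None) -> MatchSet:
    """Match each treated id to the control id with the closest score.

    With replacement; ties in distance are broken toward the lowest control
    id (earliest day).  A ``caliper`` (maximum allowed distance) moves
    treated days whose best match is farther than the cap into
    ``unmatched``.
    """
    if not scores_treated:
        raise ValueError("treated set is empty")
    if not scores_control:
        raise ValueError("control set is empty")

    c_ids = np.array(sorted(scores_control), dtype=int)
    c_scores = np.array([scores_control[i] for i in c_ids], dtype=float)
    order = np.lexsort((c_ids, c_scores))  # by score, then id
    c_ids, c_scores = c_ids[order], c_scores[order]

    t_ids = np.array(sorted(scores_treated), dtype=int)
    t_scores = np.array([scores_treated[i] for i in t_ids], dtype=float)

    pos = np.searchsorted(c_scores, t_scores)
    left = np.clip(pos - 1, 0, len(c_ids) - 1)
    right = np.clip(pos, 0, len(c_ids) - 1)
    d_left = np.abs(t_scores - c_scores[left])
    d_right = np.abs(t_scores - c_scores[right])
    # prefer strictly smaller distance; on exact ties the lower control id
    take_left = (d_left < d_right) | (
        np.isclose(d_left, d_right, rtol=0.0, atol=0.0) & (c_ids[left] < c_ids[right])
    )
    chosen = np.where(take_left, left, right)

    # equal-score runs: several controls may sit at the matched score; the
    # tie rule demands the lowest id among them
    matched_scores = c_scores[chosen]
    run_start = np.searchsorted(c_scores, matched_scores, side="left")
    same_dist = np.abs(t_scores - c_scores[run_start]) == np.abs(t_scores - matched_scores)
    chosen = np.where(same_dist & (c_ids[run_start] < c_ids[chosen]), run_start, chosen)

    control_id = c_ids[chosen]
    dist = np.abs(t_scores - c_scores[chosen])

    if caliper is not None:
        ok = dist <= caliper
    else:
        ok = np.ones(len(t_ids), dtype=bool)
    pairs = pd.DataFrame({
        "treated_id": t_ids[ok],
        "control_id": control_id[ok],
        "distance": dist[ok],
    })
    K = pairs["control_id"].value_counts().to_dict()
    return MatchSet(pairs, {int(k): int(v) for k, v in K.items()},
                    unmatched=[int(i) for i in t_ids[~ok]])


def reuse_histogram(match: MatchSet, n_controls_total: int,
                    cut_points: tuple[int, ...] = (5, 15)) -> pd.DataFrame:
    """Summary of control reuse: never/once used and cumulative shares.

    Shares at the cut points are fractions of *used* controls selected fewer
    than the cut number of times, mirroring the usual matching diagnostic.
    """
    counts = np.array(list(match.K.values()), dtype=int)
    n_used = counts.size
    rows = [
        ("never_used", n_controls_total - n_used,
         (n_controls_total - n_used) / n_controls_total if n_controls_total else np.nan),
        ("used_once", int((counts == 1).sum()),
         float((counts == 1).mean()) if n_used else np.nan),
    ]
    for c in cut_points:
        rows.append((f"used_lt_{c}", int((counts < c).sum()),
                     float((counts < c).mean()) if n_used else np.nan))
    rows.append(("max_reuse", int(counts.max()) if n_used else 0, np.nan))
    return pd.DataFrame(rows, columns=["statistic", "count", "share"])


class NearestNeighborMatcher(BaseEstimator):
    """Estimator wrapper around :func:`nn_match`.

    ``fit(scores, treated)`` takes per-day scores and the binary treatment
    vector (day ids are positional indices, i.e. design-table row numbers)
    and exposes ``match_set_``, ``pairs_`` and ``reuse_counts_``.
    """

    def __init__(self, caliper: float | None = None, on: str = "score"):
        self.caliper = caliper
        self.on = on

    def fit(self, scores, treated) -> "NearestNeighborMatcher":
        scores = np.asarray(scores, dtype=float)
        treated = np.asarray(treated).astype(int)
        if scores.shape != treated.shape:
            raise ValueError("scores and treated must align")
        if self.on == "logit":
            scores = np.log(scores / (1.0 - scores))
        elif self.on != "score":
            raise ValueError("on must be 'score' or 'logit'")
        ids = np.arange(len(scores))
        st = {int(i): float(scores[i]) for i in ids[treated == 1]}
        sc = {int(i): float(scores[i]) for i in ids[treated == 0]}
        self.match_set_ = nn_match(st, sc, caliper=self.caliper)
        self.pairs_ = self.match_set_.pairs
        self.reuse_counts_ = self.match_set_.K
        return self
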
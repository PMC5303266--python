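"""Propensity-score model: spline bases and the logistic treatment model.

The probability that a day is treated (lag 0-1 PM10 at or above the
threshold) is modelled by logistic regression on background covariates only:
season-specific day-of-week and holiday indicators, influenza / heat /
July-August indicators, a cubic regression spline on the calendar index for
medium- and long-term seasonality, and a tensor-product of thin-plate
marginal bases in lag 0-3 temperature and relative humidity.

Basis builders are exposed both as stateful objects (fit on the estimation
sample, evaluate anywhere) and as plain functions returning the matrix.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator

__all__ = [
    "BasisSpec",
    "PropensityFit",
    "PropensityScoreModel",
    "cubic_spline_basis",
    "thinplate_marginal_basis",
    "tensor_product",
    "fit_propensity",
]

SCORE_CLIP = 1e-6
_SEASONS = ("DJF", "MAM", "JJA", "SON")


@dataclass(frozen=True)
class BasisSpec:
    """Dimensions and term switches of the propensity design matrix."""

    calendar_spline_df_per_year: int = 5
    tensor_marginal_dims: tuple[int, int] = (5, 3)
    include_season_dow: bool = True
    include_holiday: bool = True
    include_influenza: bool = True
    include_heat: bool = True
    include_julyaug: bool = True
    include_calendar_spline: bool = True
    include_tensor: bool = True

    def validate(self) -> None:
        if self.calendar_spline_df_per_year < 2:
            raise ValueError("calendar_spline_df_per_year must be >= 2")
        if any(k < 2 for k in self.tensor_marginal_dims):
            raise ValueError("tensor marginal basis dimensions must be >= 2")


class CubicRegressionSpline:
    """Cubic B-spline basis with knots at quantiles, ``df`` columns.

    ``df`` counts basis columns excluding the global intercept: the full
    cubic B-spline basis has ``df + 1`` columns summing to one, and the first
    is dropped so the span together with an intercept equals the span of the
    full basis.  Interior knots sit at equally spaced quantiles of the
    training values; evaluation clamps to the training range.
    """

    def __init__(self, df: int):
        if df < 3:
            raise ValueError("df must be >= 3 for a cubic spline")
        self.df = int(df)

    def fit(self, x: np.ndarray) -> "CubicRegressionSpline":
        x = np.asarray(x, dtype=float)
        xu = np.unique(x)
        if xu.size <= self.df:
            raise ValueError(
                f"cubic spline with df={self.df} needs more than {self.df} "
                f"distinct values, got {xu.size}"
            )
        n_interior = self.df - 3
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, probs) if n_interior else np.array([])
        lo, hi = float(xu[0]), float(xu[-1])
        self.knots_ = np.concatenate([[lo] * 4, interior, [hi] * 4])
        self.bounds_ = (lo, hi)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), *self.bounds_)
        full = BSpline.design_matrix(x, self.knots_, 3).toarray()
        return full[:, 1:]


class ThinPlateBasis:
    """Rank-``k`` thin-plate regression spline basis for a 1-D input.

    Construction: the radial kernel eta(r) = r**3 is evaluated on a quantile
    grid of at most 100 distinct training values; its leading eigenvectors
    (by absolute eigenvalue) define ``k - 2`` smooth columns, to which the
    null-space columns {1, x} are appended.  ``k = 2`` yields exactly the
    null space.  Inputs are standardized internally.
    """

    def __init__(self, k: int, max_grid: int = 100):
        if k < 2:
            raise ValueError("basis dimension k must be >= 2")
        self.k = int(k)
        self.max_grid = int(max_grid)

    def fit(self, x: np.ndarray) -> "ThinPlateBasis":
        x = np.asarray(x, dtype=float)
        xu = np.unique(x)
        if xu.size < self.k:
            raise ValueError(f"k={self.k} exceeds the {xu.size} distinct values")
        self.center_ = float(x.mean())
        self.scale_ = float(x.std()) or 1.0
        z = (xu - self.center_) / self.scale_
        if z.size > self.max_grid:
            z = np.quantile(z, np.linspace(0, 1, self.max_grid))
        self.grid_ = z
        if self.k > 2:
            E = np.abs(z[:, None] - z[None, :]) ** 3
            eigval, eigvec = np.linalg.eigh(E)
            order = np.argsort(-np.abs(eigval), kind="stable")
            lam = eigval[order[: self.k - 2]]
            U = eigvec[:, order[: self.k - 2]]
            # deterministic sign: largest-magnitude loading positive
            signs = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(U.shape[1])])
            U = U * signs
            self.eigvec_ = U
            self.eigval_ = lam * signs  # fold signs into the whitening scale
        else:
            self.eigvec_ = np.empty((z.size, 0))
            self.eigval_ = np.empty(0)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.center_) / self.scale_
        cols = [np.ones_like(z), z]
        if self.k > 2:
            K = np.abs(z[:, None] - self.grid_[None, :]) ** 3
            cols.append(K @ self.eigvec_ / self.eigval_)
            return np.column_stack([cols[0], cols[1], cols[2]])
        return np.column_stack(cols)


def cubic_spline_basis(x, df: int) -> np.ndarray:
    """n x df cubic regression spline basis with quantile knots."""
    x = np.asarray(x, dtype=float)
    return CubicRegressionSpline(df).fit(x).transform(x)


def thinplate_marginal_basis(x, k: int) -> np.ndarray:
    """n x k thin-plate regression spline basis (null space {1, x})."""
    x = np.asarray(x, dtype=float)
    return ThinPlateBasis(k).fit(x).transform(x)


def tensor_product(bx: np.ndarray, by: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker product; column (a, b) is bx[:, a] * by[:, b]."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    if bx.shape[0] != by.shape[0]:
        raise ValueError(f"row mismatch: {bx.shape[0]} vs {by.shape[0]}")
    return np.einsum("ij,ik->ijk", bx, by).reshape(bx.shape[0], -1)


@dataclass
class PropensityFit:
    """Fitted propensity model: coefficients, scores and diagnostics."""

    beta: np.ndarray
    column_names: list[str]
    scores: np.ndarray
    loglik: float
    n_iter: int
    max_abs_score_eq: float
    pruned_columns: list[str] = field(default_factory=list)
    spec: BasisSpec = field(default_factory=BasisSpec)

    def to_json(self) -> str:
        return json.dumps({
            "beta": dict(zip(self.column_names, self.beta.tolist())),
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "max_abs_score_eq": self.max_abs_score_eq,
            "pruned_columns": self.pruned_columns,
            "spec": asdict(self.spec),
        }, indent=2)


class _DesignBuilder:
    """Assembles the propensity design matrix; stateful for out-of-sample use."""

    def __init__(self, spec: BasisSpec):
        self.spec = spec

    def fit(self, design: pd.DataFrame) -> "_DesignBuilder":
        if self.spec.include_calendar_spline:
            n_years = len(design) / 365.25
            df_cal = max(3, round(self.spec.calendar_spline_df_per_year * n_years))
            self.cal_spline_ = CubicRegressionSpline(df_cal).fit(
                design["calendar_index"].to_numpy(float))
        if self.spec.include_tensor:
            k1, k2 = self.spec.tensor_marginal_dims
            self.tp_temp_ = ThinPlateBasis(k1).fit(design["temp03"].to_numpy(float))
            self.tp_hum_ = ThinPlateBasis(k2).fit(design["humidity"].to_numpy(float))
        return self

    def transform(self, design: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        n = len(design)
        cols: list[np.ndarray] = [np.ones(n)]
        names: list[str] = ["intercept"]
        season = design["season"].to_numpy()
        if self.spec.include_season_dow:
            dow = design["day_of_week"].to_numpy()
            for s in _SEASONS:
                for d in range(1, 7):  # Monday is the reference day
                    cols.append(((season == s) & (dow == d)).astype(float))
                    names.append(f"dow{d}:{s}")
        if self.spec.include_holiday:
            hol = design["holiday"].to_numpy(float)
            for s in _SEASONS:
                cols.append(hol * (season == s))
                names.append(f"holiday:{s}")
        for flag, include in (("influenza", self.spec.include_influenza),
                              ("heat", self.spec.include_heat),
                              ("julyaug", self.spec.include_julyaug)):
            if include:
                cols.append(design[flag].to_numpy(float))
                names.append(flag)
        if self.spec.include_calendar_spline:
            cal = self.cal_spline_.transform(design["calendar_index"].to_numpy(float))
            cols.extend(cal.T)
            names.extend(f"cal_s{i}" for i in range(cal.shape[1]))
        if self.spec.include_tensor:
            te = tensor_product(
                self.tp_temp_.transform(design["temp03"].to_numpy(float)),
                self.tp_hum_.transform(design["humidity"].to_numpy(float)))
            cols.extend(te.T)
            k2 = self.spec.tensor_marginal_dims[1]
            names.extend(f"te_t{i // k2}_h{i % k2}" for i in range(te.shape[1]))
        return np.column_stack(cols), names


def _prune_collinear(X: np.ndarray, names: list[str],
                     tol: float = 1e-9) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop columns until full column rank (QR with pivoting on scaled columns)."""
    norms = np.linalg.norm(X, axis=0)
    norms[norms == 0] = 1.0
    _, R, piv = scipy.linalg.qr(X / norms, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > tol * diag[0]))
    keep = np.sort(piv[:rank])
    dropped = [names[j] for j in sorted(set(range(X.shape[1])) - set(keep))]
    return X[:, keep], [names[j] for j in keep], dropped


class PropensityScoreModel(BaseEstimator):
    """Logistic propensity model over the spline covariate basis.

    Parameters mirror :class:`BasisSpec`; the model is fit by IRLS maximum
    likelihood (no penalization -- the spline ranks are fixed a priori).
    Fitted scores are clipped away from 0 and 1 so that downstream matching
    always has a finite ordering, and a warning is emitted if coefficients
    suggest separation.

    Attributes (after ``fit``): ``coef_``, ``column_names_``,
    ``propensity_``, ``fit_`` (a :class:`PropensityFit`).
    """

    def __init__(self, calendar_spline_df_per_year: int = 5,
                 tensor_marginal_dims: tuple[int, int] = (5, 3),
                 include_season_dow: bool = True, include_holiday: bool = True,
                 include_influenza: bool = True, include_heat: bool = True,
                 include_julyaug: bool = True, include_calendar_spline: bool = True,
                 include_tensor: bool = True, clip: float = SCORE_CLIP):
        self.calendar_spline_df_per_year = calendar_spline_df_per_year
        self.tensor_marginal_dims = tensor_marginal_dims
        self.include_season_dow = include_season_dow
        self.include_holiday = include_holiday
        self.include_influenza = include_influenza
        self.include_heat = include_heat
        self.include_julyaug = include_julyaug
        self.include_calendar_spline = include_calendar_spline
        self.include_tensor = include_tensor
        self.clip = clip

    def _spec(self) -> BasisSpec:
        return BasisSpec(
            calendar_spline_df_per_year=self.calendar_spline_df_per_year,
            tensor_marginal_dims=tuple(self.tensor_marginal_dims),
            include_season_dow=self.include_season_dow,
            include_holiday=self.include_holiday,
            include_influenza=self.include_influenza,
            include_heat=self.include_heat,
            include_julyaug=self.include_julyaug,
            include_calendar_spline=self.include_calendar_spline,
            include_tensor=self.include_tensor,
        )

    def fit(self, design: pd.DataFrame, y=None) -> "PropensityScoreModel":
        spec = self._spec()
        spec.validate()
        w = design["w"].to_numpy(float)
        if w.min() == w.max():
            raise ValueError("both treatment groups must be nonempty")
        self.builder_ = _DesignBuilder(spec).fit(design)
        X, names = self.builder_.transform(design)
        if X.shape[1] >= X.shape[0]:
            raise ValueError("design matrix has more columns than rows")
        X, names, dropped = _prune_collinear(X, names)
        res = sm.GLM(w, X, family=sm.families.Binomial()).fit(
            maxiter=200, tol=1e-10)
        eta = X @ res.params
        scores = 1.0 / (1.0 + np.exp(-eta))
        score_eq = X.T @ (w - scores)
        # |eta| > 36 means the fitted probability is 0/1 to double precision,
        # the practical signature of (quasi-)separation under IRLS
        if np.abs(eta).max() > 36.0:
            warnings.warn("possible separation: fitted propensities pinned at "
                          "0/1; scores are clipped for matching", RuntimeWarning)
        self.coef_ = res.params
        self.column_names_ = names
        self.pruned_columns_ = dropped
        self.propensity_ = np.clip(scores, self.clip, 1.0 - self.clip)
        self.fit_ = PropensityFit(
            beta=res.params, column_names=names, scores=self.propensity_,
            loglik=float(res.llf), n_iter=int(res.fit_history["iteration"]),
            max_abs_score_eq=float(np.abs(score_eq).max()),
            pruned_columns=dropped, spec=spec,
        )
        return self

    def predict_proba(self, design: pd.DataFrame) -> np.ndarray:
        X, names = self.builder_.transform(design)
        keep = [names.index(c) for c in self.column_names_]
        eta = X[:, keep] @ self.coef_
        p = 1.0 / (1.0 + np.exp(-eta))
        return np.clip(p, self.clip, 1.0 - self.clip)


def fit_propensity(design: pd.DataFrame, spec: BasisSpec | None = None) -> PropensityFit:
    """Fit the logistic propensity model; returns the :class:`PropensityFit`."""
    spec = spec or BasisSpec()
    model = PropensityScoreModel(
        calendar_spline_df_per_year=spec.calendar_spline_df_per_year,
        tensor_marginal_dims=spec.tensor_marginal_dims,
        include_season_dow=spec.include_season_dow,
        include_holiday=spec.include_holiday,
        include_influenza=spec.include_influenza,
        include_heat=spec.include_heat,
        include_julyaug=spec.include_julyaug,
        include_calendar_spline=spec.include_calendar_spline,
        include_tensor=spec.include_tensor,
    ).fit(design)
    return model.fit_
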
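"""Nutritional response-surface estimation.

For each trait and group (typically each sex), the effect of protein and
carbohydrate intake on a trait is summarized by a second-order response
surface on the z-scale:

    trait = b0 + beta_P * P + beta_C * C
               + gamma_PP * P^2 + gamma_CC * C^2 + gamma_PC * P*C + eps

Estimation is two-stage, following standard selection-gradient practice:
the *linear* gradients (beta) come from the first-order model only, so they
estimate average directional effects uncontaminated by curvature terms; the
*quadratic* and *correlational* gradients (gamma) come from the full
second-order model.  Quadratic coefficients are reported as raw regression
coefficients (no doubling convention).  With n observations the linear terms
carry n - 3 residual df and the nonlinear terms n - 6.

A thin-plate spline smoother (:class:`ThinPlateSpline`) turns the raw
(P, C, trait) triples into a smooth nutritional landscape for visualization
and peak location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Delaunay
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data_model import StandardizedTable

TERMS = ("P", "C", "PxP", "CxC", "PxC")


@dataclass
class GradientSet:
    """Linear, quadratic and correlational nutritional gradients for one
    trait in one group, with per-term SE, t, df and two-sided p."""

    group: str
    trait: str
    n: int
    estimates: dict[str, dict[str, float]]  # term -> {coef, se, t, df, p}

    @property
    def linear(self) -> np.ndarray:
        return np.array([self.estimates["P"]["coef"], self.estimates["C"]["coef"]])

    @property
    def quadratic(self) -> np.ndarray:
        return np.array([self.estimates["PxP"]["coef"], self.estimates["CxC"]["coef"]])

    @property
    def correlational(self) -> float:
        return self.estimates["PxC"]["coef"]

    @property
    def gamma(self) -> np.ndarray:
        """Symmetric 2x2 matrix of nonlinear gradients (raw coefficients)."""
        g11, g22 = self.quadratic
        g12 = self.correlational
        return np.array([[g11, g12], [g12, g22]])

    def table(self) -> pd.DataFrame:
        rows = [{"term": t, **self.estimates[t]} for t in TERMS]
        df = pd.DataFrame(rows)
        df.insert(0, "trait", self.trait)
        df.insert(0, "group", self.group)
        return df


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """Plain least squares returning (coef, se, residual df)."""
    n, p = X.shape
    xtx = X.T @ X
    cond = np.linalg.cond(xtx)
    if cond > 1e10:
        raise ValueError(
            "rank-deficient design: P and C columns (or their products) are "
            "collinear — e.g. all observations lie on a single nutritional rail"
        )
    coef = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ coef
    df = n - p
    s2 = float(resid @ resid) / df
    se = np.sqrt(np.diag(s2 * np.linalg.inv(xtx)))
    return coef, se, df


class ResponseSurfaceRegression(BaseEstimator, RegressorMixin):
    """Two-stage response-surface fit mapping (P, C) intake to a trait.

    Parameters
    ----------
    order:
        ``"full"`` (default) fits linear gradients from the first-order model
        and nonlinear gradients from the second-order model; ``"linear"``
        stops at the first-order model.

    Attributes
    ----------
    beta_ : (2,) linear gradients (P, C) from the first-order model
    gamma_ : (2, 2) symmetric nonlinear-gradient matrix (full model)
    intercept_ : intercept of the full model used for prediction
    estimates_ : per-term {coef, se, t, df, p}
    """

    def __init__(self, order: str = "full"):
        self.order = order

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): P and C intake")
        mask = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
        X, y = X[mask], y[mask]
        n = len(y)
        min_n = 7 if self.order == "full" else 4
        if n < min_n:
            raise ValueError(f"need at least {min_n} complete rows, got {n}")
        P, C = X[:, 0], X[:, 1]
        ones = np.ones(n)

        if np.ptp(y) == 0:
            # a constant trait has no gradients of any order
            zero = {"coef": 0.0, "se": 0.0, "t": 0.0, "df": n - 6, "p": 1.0}
            self.estimates_ = {t: dict(zero) for t in TERMS}
            self.estimates_["P"]["df"] = self.estimates_["C"]["df"] = n - 3
            self.beta_ = np.zeros(2)
            self.gamma_ = np.zeros((2, 2))
            self.intercept_ = float(y[0])
            self._coef_full = np.array([y[0], 0, 0, 0, 0, 0.0])
            self.n_ = n
            return self

        est: dict[str, dict[str, float]] = {}
        Xl = np.column_stack([ones, P, C])
        coef_l, se_l, df_l = _ols(Xl, y)
        for i, term in enumerate(("P", "C"), start=1):
            est[term] = _term(coef_l[i], se_l[i], df_l)
        self.beta_ = coef_l[1:3].copy()
        self.intercept_ = float(coef_l[0])
        self._coef_full = None

        if self.order == "full":
            Xf = np.column_stack([ones, P, C, P * P, C * C, P * C])
            coef_f, se_f, df_f = _ols(Xf, y)
            for i, term in enumerate(("PxP", "CxC", "PxC"), start=3):
                est[term] = _term(coef_f[i], se_f[i], df_f)
            # raw PxC coefficient on the off-diagonal (no halving convention)
            self.gamma_ = np.array(
                [[coef_f[3], coef_f[5]], [coef_f[5], coef_f[4]]]
            )
            self.intercept_ = float(coef_f[0])
            self._coef_full = coef_f
        self.n_ = n
        self.estimates_ = est
        return self

    def predict(self, X):
        check_is_fitted(self, "estimates_")
        X = np.asarray(X, dtype=float)
        P, C = X[:, 0], X[:, 1]
        if self._coef_full is None:
            return self.intercept_ + self.beta_[0] * P + self.beta_[1] * C
        b = self._coef_full
        return b[0] + b[1] * P + b[2] * C + b[3] * P * P + b[4] * C * C + b[5] * P * C

    def gradient_set(self, group: str = "", trait: str = "") -> GradientSet:
        check_is_fitted(self, "estimates_")
        return GradientSet(group=group, trait=trait, n=self.n_,
                           estimates=dict(self.estimates_))


def _term(coef: float, se: float, df: int) -> dict[str, float]:
    t = coef / se if se > 0 else 0.0
    p = 2 * stats.t.sf(abs(t), df) if se > 0 else 1.0
    return {"coef": float(coef), "se": float(se), "t": float(t),
            "df": int(df), "p": float(p)}


def fit_gradients(
    data: StandardizedTable | pd.DataFrame,
    trait: str,
    group: str,
    group_col: str = "sex",
) -> GradientSet:
    """Fit the nutritional gradients for one trait within one group.

    ``data`` is a z-standardized intake table; ``group`` selects rows by
    ``group_col`` (default the sex column).
    """
    df = data.data if isinstance(data, StandardizedTable) else data
    sub = df[df[group_col] == group]
    if len(sub) == 0:
        raise ValueError(f"no rows with {group_col} == {group!r}")
    model = ResponseSurfaceRegression().fit(
        sub[["p_intake", "c_intake"]].to_numpy(), sub[trait].to_numpy()
    )
    return model.gradient_set(group=group, trait=trait)


# ---------------------------------------------------------------------------
# thin-plate spline landscape


def _tps_basis(r: np.ndarray) -> np.ndarray:
    # r^2 log r, continuously extended by 0 at r = 0
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out


class ThinPlateSpline(BaseEstimator, RegressorMixin):
    """Thin-plate-spline smoother over (P, C) intake space.

    The fitted surface minimizes residual sum of squares plus ``smoothing``
    times the bending energy, using the radial basis r^2 log r with an affine
    null space.  ``smoothing="gcv"`` selects the penalty by generalized
    cross-validation over a log-spaced grid.

    Attributes
    ----------
    smoothing_ : the penalty actually used
    gcv_score_ : GCV score at ``smoothing_`` (when selected by GCV)
    """

    def __init__(self, smoothing: float | str = "gcv",
                 gcv_grid: np.ndarray | None = None):
        self.smoothing = smoothing
        self.gcv_grid = gcv_grid

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        uniq = np.unique(X, axis=0)
        if len(uniq) < 3:
            raise ValueError(
                "thin-plate spline needs at least 3 distinct (P, C) points; "
                f"got {len(uniq)}"
            )
        self._X = X
        self._y = y
        n = len(y)
        d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=-1)
        K = _tps_basis(d)
        T = np.column_stack([np.ones(n), X])  # affine null space

        if self.smoothing == "gcv":
            grid = self.gcv_grid
            if grid is None:
                grid = np.logspace(-8, 2, 41)
            scores = [self._gcv(K, T, y, lam) for lam in grid]
            i = int(np.argmin(scores))
            lam = float(grid[i])
            self.gcv_score_ = float(scores[i])
        else:
            lam = float(self.smoothing)
        self.smoothing_ = lam
        self._w, self._c = self._solve(K, T, y, lam)
        self.fitted_values_ = K @ self._w + T @ self._c
        return self

    @staticmethod
    def _solve(K, T, y, lam):
        n = len(y)
        M = np.block([[K + n * lam * np.eye(n), T],
                      [T.T, np.zeros((T.shape[1], T.shape[1]))]])
        rhs = np.concatenate([y, np.zeros(T.shape[1])])
        try:
            sol = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(M, rhs, rcond=None)[0]
        return sol[:n], sol[n:]

    def _gcv(self, K, T, y, lam):
        n = len(y)
        q = T.shape[1]
        M = np.block([[K + n * lam * np.eye(n), T],
                      [T.T, np.zeros((q, q))]])
        try:
            Minv = np.linalg.inv(M)
        except np.linalg.LinAlgError:
            return np.inf
        # influence matrix A with yhat = A y
        A = K @ Minv[:n, :n] + T @ Minv[n:, :n]
        resid = y - A @ y
        denom = n - np.trace(A)
        if denom <= 1e-8:
            return np.inf
        return n * float(resid @ resid) / denom**2

    def gcv_at(self, lam: float) -> float:
        """GCV score at an arbitrary penalty on the fitted data."""
        check_is_fitted(self, "smoothing_")
        d = np.linalg.norm(self._X[:, None, :] - self._X[None, :, :], axis=-1)
        K = _tps_basis(d)
        T = np.column_stack([np.ones(len(self._y)), self._X])
        return self._gcv(K, T, self._y, lam)

    def predict(self, X):
        check_is_fitted(self, "smoothing_")
        X = np.asarray(X, dtype=float)
        d = np.linalg.norm(X[:, None, :] - self._X[None, :, :], axis=-1)
        K = _tps_basis(d)
        T = np.column_stack([np.ones(len(X)), X])
        return K @ self._w + T @ self._c


@dataclass
class LandscapeGrid:
    """Gridded nutritional landscape for one trait in one group."""

    p_grid: np.ndarray          # (nx,) protein-intake axis
    c_grid: np.ndarray          # (ny,) carbohydrate-intake axis
    values: np.ndarray          # (ny, nx) predicted trait values
    in_hull: np.ndarray         # (ny, nx) bool, inside the data convex hull
    smoothing: float
    method: str = "thin-plate spline"

    def peak(self, within_hull: bool = True) -> tuple[float, float, float]:
        """(P, C, value) at the grid maximum, optionally hull-restricted."""
        vals = np.where(self.in_hull, self.values, -np.inf) if within_hull \
            else self.values
        iy, ix = np.unravel_index(np.argmax(vals), vals.shape)
        return float(self.p_grid[ix]), float(self.c_grid[iy]), float(vals[iy, ix])

    def value_at(self, p: float, c: float) -> float:
        """Bilinear interpolation of the gridded surface at (p, c)."""
        from scipy.interpolate import RegularGridInterpolator

        itp = RegularGridInterpolator((self.c_grid, self.p_grid), self.values,
                                      bounds_error=True)
        return float(itp([[c, p]])[0])

    def contains(self, p: float, c: float) -> bool:
        in_box = (self.p_grid[0] <= p <= self.p_grid[-1]
                  and self.c_grid[0] <= c <= self.c_grid[-1])
        if not in_box:
            return False
        ix = int(np.argmin(np.abs(self.p_grid - p)))
        iy = int(np.argmin(np.abs(self.c_grid - c)))
        return bool(self.in_hull[iy, ix])

    def to_long(self) -> pd.DataFrame:
        pp, cc = np.meshgrid(self.p_grid, self.c_grid)
        return pd.DataFrame({"p_intake": pp.ravel(), "c_intake": cc.ravel(),
                             "value": self.values.ravel(),
                             "in_hull": self.in_hull.ravel()})


def fit_landscape(
    data: StandardizedTable | pd.DataFrame,
    trait: str,
    group: str | None = None,
    smoothing: float | str = "gcv",
    n_grid: int = 50,
    group_col: str = "sex",
) -> LandscapeGrid:
    """Fit a thin-plate-spline nutritional landscape and grid it.

    The grid is rectangular over the observed intake bounding box; cells
    outside the convex hull of the data are flagged so extrapolated regions
    are never reported as supported.
    """
    df = data.data if isinstance(data, StandardizedTable) else data
    if group is not None:
        df = df[df[group_col] == group]
    sub = df[["p_intake", "c_intake", trait]].dropna()
    X = sub[["p_intake", "c_intake"]].to_numpy()
    if len(np.unique(X, axis=0)) < 10:
        raise ValueError("need at least 10 distinct (P, C) points for a landscape")
    spline = ThinPlateSpline(smoothing=smoothing).fit(X, sub[trait].to_numpy())
    p_grid = np.linspace(X[:, 0].min(), X[:, 0].max(), n_grid)
    c_grid = np.linspace(X[:, 1].min(), X[:, 1].max(), n_grid)
    pp, cc = np.meshgrid(p_grid, c_grid)
    pts = np.column_stack([pp.ravel(), cc.ravel()])
    values = spline.predict(pts).reshape(n_grid, n_grid)
    hull = Delaunay(X)
    in_hull = (hull.find_simplex(pts) >= 0).reshape(n_grid, n_grid)
    return LandscapeGrid(p_grid=p_grid, c_grid=c_grid, values=values,
                         in_hull=in_hull, smoothing=spline.smoothing_)
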
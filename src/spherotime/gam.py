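"""Penalized regression-spline smoothing with GCV smoothness selection.

A small GAM engine for one smooth term: ``y ~ s(t, k)``.  The smooth is a
cubic B-spline basis of dimension ``k`` with knots at quantiles of ``t`` and a
second-derivative (curvature) penalty.  The smoothing parameter is chosen by
generalized cross-validation, with the model-complexity term of the GCV score
inflated by a factor ``gamma`` (larger gamma -> smoother fits).

The significance of the smooth term is reported as the exact F test of the
unpenalized k-dimensional spline regression against the constant model.  Under
Gaussian noise this p-value is exactly uniform when the signal is constant,
which keeps downstream FDR control honest; the penalized fit (used for fitted
values and effective degrees of freedom) would give an anti-conservative test
if its data-driven edf were plugged into the F reference distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = ["GamFit", "fit_gam_smooth", "fit_gam_many", "SplineBasis"]

#: -log10(p) is capped here when p underflows to 0.
NEGLOG10_P_CAP = 300.0


@dataclass
class GamFit:
    """Result of a single penalized spline fit."""

    smooth_p: float
    edf: float
    k: int
    gamma: float
    fitted: np.ndarray
    lam: float
    rss: float
    p_adjusted: float | None = None

    @property
    def neglog10_p(self) -> float:
        if self.smooth_p <= 0:
            return NEGLOG10_P_CAP
        return min(-np.log10(self.smooth_p), NEGLOG10_P_CAP)


class SplineBasis:
    """Cubic B-spline design and curvature penalty for a fixed time vector.

    Building the basis once and reusing it across many response vectors is
    what makes window-wise per-gene fitting cheap.
    """

    degree = 3

    def __init__(self, t: np.ndarray, k: int):
        t = np.asarray(t, dtype=float)
        if t.ndim != 1:
            raise ValueError("t must be one-dimensional")
        if k < 4:
            raise ValueError("basis dimension k must be >= 4 for cubic splines")
        if np.ptp(t) <= 0:
            raise ValueError("t is constant; smooth fit is rank deficient")
        self.t = t
        self.k = int(k)
        lo, hi = float(t.min()), float(t.max())
        n_interior = k - (self.degree + 1)
        if n_interior > 0:
            qs = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
            interior = np.quantile(np.unique(t), qs)
        else:
            interior = np.array([])
        self.knots = np.concatenate(
            [[lo] * (self.degree + 1), interior, [hi] * (self.degree + 1)]
        )
        self.X = interpolate.BSpline.design_matrix(
            t, self.knots, self.degree, extrapolate=True
        ).toarray()
        self.S = self._penalty_matrix()
        self.XtX = self.X.T @ self.X
        # scale-equalising constant so the lambda grid is unitless
        self.lam_scale = np.trace(self.XtX) / max(np.trace(self.S), 1e-300)

    def _penalty_matrix(self) -> np.ndarray:
        """Exact Gram matrix of second derivatives of the basis functions.

        The second derivative of a cubic B-spline is piecewise linear, so the
        integrand on each knot interval is a quadratic; 2-point Gauss-Legendre
        integrates it exactly.
        """
        k = self.k
        S = np.zeros((k, k))
        gl_x, gl_w = np.polynomial.legendre.leggauss(2)
        uniq = np.unique(self.knots)
        eye = np.eye(k)
        for a, b in zip(uniq[:-1], uniq[1:]):
            if b <= a:
                continue
            mid, half = (a + b) / 2.0, (b - a) / 2.0
            pts = mid + half * gl_x
            D2 = np.empty((len(pts), k))
            for j in range(k):
                spl = interpolate.BSpline(self.knots, eye[j], self.degree)
                D2[:, j] = spl.derivative(2)(pts)
            S += (D2 * (gl_w * half)[:, None]).T @ D2
        return S

    def evaluate(self, t_new: np.ndarray) -> np.ndarray:
        return interpolate.BSpline.design_matrix(
            np.asarray(t_new, dtype=float), self.knots, self.degree, extrapolate=True
        ).toarray()


def _lambda_grid(n_lambda: int = 50) -> np.ndarray:
    # descending, so ties in GCV resolve toward the smoothest fit; the upper
    # end is kept moderate so the penalty null space (constant + linear)
    # stays numerically exact at maximal smoothing
    return np.logspace(4.0, -7.0, n_lambda)


def fit_gam_many(
    Y: np.ndarray,
    t: np.ndarray,
    k: int = 10,
    gamma: float = 1.0,
    n_lambda: int = 50,
    basis: SplineBasis | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit ``y_g ~ s(t, k)`` for every column g of ``Y`` over a shared lambda grid.

    Returns ``(p, edf, fitted, lam)`` where ``p`` is the exact
    smooth-vs-constant F-test p-value per column, ``edf`` the effective
    degrees of freedom of the GCV-selected penalized fit (smooth term only,
    intercept excluded), ``fitted`` the penalized fitted values (n x G) and
    ``lam`` the selected smoothing parameters.

    All linear algebra is shared across columns: for each lambda we factorise
    (X'X + lam*S) once and evaluate every response against it.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    n, G = Y.shape
    t = np.asarray(t, dtype=float)
    if len(t) != n:
        raise ValueError("Y rows and t length differ")
    if basis is None:
        basis = SplineBasis(t, k)
    if n < basis.k + 2:
        raise ValueError(f"need at least k + 2 = {basis.k + 2} observations, got {n}")

    X, S, XtX = basis.X, basis.S, basis.XtX
    XtY = X.T @ Y
    lams = _lambda_grid(n_lambda) * basis.lam_scale

    best_gcv = np.full(G, np.inf)
    best_rss = np.empty(G)
    best_edf = np.empty(G)
    best_lam = np.empty(G)
    best_fit = np.empty((n, G))

    # floor the GCV score so that exact or near-exact fits (rss ~ 0 at every
    # lambda, e.g. constant or purely linear responses) tie and the tie
    # resolves toward the smoothest lambda (the grid is descending)
    rss0_all = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    y_scale = np.sum(Y**2, axis=0)
    gcv_floor = 1e-10 * (rss0_all + 1e-8 * y_scale + 1e-300) / n

    for lam in lams:
        M = XtX + lam * S
        try:
            c = cho_factor(M)
        except np.linalg.LinAlgError:
            continue
        coef = cho_solve(c, XtY)
        fitted = X @ coef
        rss = np.sum((Y - fitted) ** 2, axis=0)
        edf_total = float(np.trace(cho_solve(c, XtX)))
        denom = n - gamma * edf_total
        if denom <= 0:
            continue
        gcv = np.maximum(n * rss / denom**2, gcv_floor)
        better = gcv < best_gcv * (1.0 - 1e-9)
        if np.any(better):
            best_gcv[better] = gcv[better]
            best_rss[better] = rss[better]
            best_edf[better] = edf_total
            best_lam[better] = lam
            best_fit[:, better] = fitted[:, better]

    # exact F test: unpenalized spline fit vs constant model
    beta_un, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted_un = X @ beta_un
    rss1 = np.sum((Y - fitted_un) ** 2, axis=0)
    rank = np.linalg.matrix_rank(X)
    rss0 = np.sum((Y - Y.mean(axis=0)) ** 2, axis=0)
    df1, df2 = rank - 1, n - rank
    if df2 <= 0:
        raise ValueError("not enough observations for the smooth-term test")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    p = np.where(
        rss0 <= 0,
        1.0,  # constant response: nothing to test
        np.where(rss1 <= 0, 0.0, stats.f.sf(F, df1, df2)),
    )
    edf_smooth = np.maximum(best_edf - 1.0, 0.0)
    return np.asarray(p, dtype=float), edf_smooth, best_fit, best_lam


def fit_gam_smooth(
    y: np.ndarray, t: np.ndarray, k: int = 10, gamma: float = 1.0
) -> GamFit:
    """Penalized spline fit of a single series ``y`` on ``t``.

    Mirrors an ``mgcv``-style call ``gam(y ~ s(t, k), method="GCV.Cp",
    gamma=gamma)``: the curvature penalty weight is chosen to minimise the
    GCV score with its degrees-of-freedom term inflated by ``gamma``.
    """
    y = np.asarray(y, dtype=float)
    p, edf, fitted, lam = fit_gam_many(y.reshape(-1, 1), t, k=k, gamma=gamma)
    n = len(y)
    rss = float(np.sum((y - fitted[:, 0]) ** 2))
    return GamFit(
        smooth_p=float(p[0]),
        edf=float(edf[0]),
        k=int(k),
        gamma=float(gamma),
        fitted=fitted[:, 0],
        lam=float(lam[0]),
        rss=rss,
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg FDR adjustment (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
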
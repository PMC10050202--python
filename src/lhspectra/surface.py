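"""Binomial smooth surfaces of extinction risk over the functional space.

A species' probability of being high-risk (or of being affected by a
given threat) is modelled as a logistic generalized additive model with a
single 2-D smooth of the (PC1, PC2) coordinates.  The smooth is a tensor
product of cubic B-spline bases (8 marginal basis functions per axis by
default) with a second-order difference penalty on each margin; the
smoothing parameter is chosen by generalized cross-validation (GCV) over
a log-spaced grid inside penalized IRLS.

The significance of the smooth is a Wald-type test: the penalized fit's
smooth component of the linear predictor is compared against the constant
model using a rank-truncated pseudo-inverse of its covariance, with the
rounded effective degrees of freedom as the reference chi-square df.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

__all__ = [
    "SurfaceModel",
    "fit_binomial_surface",
    "smooth_term_test",
    "predict_surface",
]

DEFAULT_K = 8            # marginal basis dimension per axis
PENALTY_ORDER = 2        # difference-penalty order
LAMBDA_GRID = np.logspace(-4, 6, 21)
MAX_ABS_COEF = 50.0      # separation guard on the link scale


def _bspline_basis(x: np.ndarray, xmin: float, xmax: float, k: int) -> np.ndarray:
    """Cubic B-spline design matrix with k basis functions on [xmin, xmax]."""
    degree = 3
    n_inner = k - degree - 1
    if n_inner < 0:
        raise ValueError("need at least 4 basis functions for a cubic spline")
    inner = np.linspace(xmin, xmax, n_inner + 2)[1:-1]
    knots = np.concatenate([[xmin] * (degree + 1), inner, [xmax] * (degree + 1)])
    xc = np.clip(x, xmin, xmax)
    design = BSpline.design_matrix(xc, knots, degree).toarray()
    return design


def _difference_penalty(k: int, order: int = PENALTY_ORDER) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _constraint_basis(m: int) -> np.ndarray:
    """Orthonormal basis of the sum-to-zero subspace of R^m (m x m-1).

    B-spline tensor rows sum to 1, making the constant coefficient
    direction collinear with the intercept; projecting coefficients onto
    this subspace removes that exact rank deficiency.
    """
    ones = np.full((m, 1), 1.0 / np.sqrt(m))
    Q, _ = np.linalg.qr(np.hstack([ones, np.eye(m)[:, : m - 1]]))
    Z = Q[:, 1:m]
    # deterministic sign convention
    for j in range(Z.shape[1]):
        i = np.argmax(np.abs(Z[:, j]))
        if Z[i, j] < 0:
            Z[:, j] = -Z[:, j]
    return Z


@dataclass(frozen=True)
class SurfaceModel:
    """Fitted binomial smooth surface."""

    coefficients: np.ndarray     # [intercept, smooth coefs (centred basis)]
    lam: float                   # chosen smoothing parameter
    edf: float                   # effective degrees of freedom of the fit
    chi2: float
    p_value: float
    k: int                       # marginal basis dimension
    x_range: tuple
    y_range: tuple
    cov_unscaled: np.ndarray     # penalized ("Bayesian") coefficient covariance
    centring: np.ndarray         # column means removed from the smooth basis
    dispersion: float = 1.0
    link: str = "logit"
    separation_warning: bool = False

    def basis(self, pc1, pc2) -> np.ndarray:
        """Design matrix [1, constrained tensor basis] at new points."""
        pc1 = np.asarray(pc1, dtype=float)
        pc2 = np.asarray(pc2, dtype=float)
        Bx = _bspline_basis(pc1, *self.x_range, self.k)
        By = _bspline_basis(pc2, *self.y_range, self.k)
        T = np.einsum("ij,ik->ijk", Bx, By).reshape(len(pc1), -1)
        T = (T - self.centring) @ _constraint_basis(self.k * self.k)
        return np.column_stack([np.ones(len(pc1)), T])

    def predict(self, pc1, pc2, link_scale: bool = False) -> np.ndarray:
        eta = self.basis(pc1, pc2) @ self.coefficients
        if link_scale:
            return eta
        return 1.0 / (1.0 + np.exp(-eta))


def _pirls(X, S, y, lam, max_iter=100, tol=1e-8, ridge=0.0):
    """Penalized IRLS for a Bernoulli-logit model.

    Returns (beta, XtWX, edf, dev) at convergence.
    """
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    # tiny fixed ridge keeps the penalty-null-space directions identified
    # when the data are sparse relative to the basis
    P = lam * S + max(ridge, 1e-7) * np.eye(p)
    dev_old = np.inf
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        XtWX = XtW @ X
        A = XtWX + P
        beta_new = np.linalg.solve(A, XtW @ z)
        mu_new = 1.0 / (1.0 + np.exp(-np.clip(X @ beta_new, -30, 30)))
        dev = -2.0 * np.sum(y * np.log(np.clip(mu_new, 1e-12, None))
                            + (1 - y) * np.log(np.clip(1 - mu_new, 1e-12, None)))
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol or abs(dev_old - dev) < tol * (abs(dev) + 1):
            break
        dev_old = dev
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = np.clip(mu * (1 - mu), 1e-10, None)
    XtWX = (X.T * w) @ X
    A = XtWX + P
    edf = float(np.trace(np.linalg.solve(A, XtWX)))
    dev = -2.0 * np.sum(y * np.log(np.clip(mu, 1e-12, None))
                        + (1 - y) * np.log(np.clip(1 - mu, 1e-12, None)))
    return beta, XtWX, A, edf, dev


def fit_binomial_surface(
    space: pd.DataFrame,
    labels,
    k: int = DEFAULT_K,
    lambda_grid=LAMBDA_GRID,
) -> SurfaceModel:
    """Fit the 2-D binomial smooth of a 0/1 label over (PC1, PC2).

    The smoothing parameter minimises the GCV score
    ``n * deviance / (n - edf)^2`` over ``lambda_grid``.  A fit whose
    coefficients exceed a separation guard is refit with a small ridge
    and flagged.  Deterministic given data and configuration.
    """
    pc1 = space["pc1"].to_numpy(dtype=float)
    pc2 = space["pc2"].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=float)
    if len(y) != len(pc1):
        raise ValueError("labels must align with the functional space rows")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class; nothing to model")

    x_range = (float(pc1.min()), float(pc1.max()))
    y_range = (float(pc2.min()), float(pc2.max()))
    Bx = _bspline_basis(pc1, *x_range, k)
    By = _bspline_basis(pc2, *y_range, k)
    T = np.einsum("ij,ik->ijk", Bx, By).reshape(len(pc1), -1)
    centring = T.mean(axis=0)
    Z = _constraint_basis(k * k)
    Tc = (T - centring) @ Z
    X = np.column_stack([np.ones(len(pc1)), Tc])

    Sx = _difference_penalty(k)
    Ik = np.eye(k)
    S_smooth = Z.T @ (np.kron(Sx, Ik) + np.kron(Ik, Sx)) @ Z
    S = np.zeros((X.shape[1], X.shape[1]))
    S[1:, 1:] = S_smooth

    n = len(y)
    best = None
    for lam in np.atleast_1d(lambda_grid):
        beta, XtWX, A, edf, dev = _pirls(X, S, y, lam)
        gcv = n * dev / max(n - edf, 1e-6) ** 2
        if best is None or gcv < best[0]:
            best = (gcv, lam, beta, XtWX, A, edf, dev)
    _, lam, beta, XtWX, A, edf, dev = best

    separation = bool(np.max(np.abs(beta)) > MAX_ABS_COEF)
    if separation:
        beta, XtWX, A, edf, dev = _pirls(X, S, y, lam, ridge=1e-3)

    # penalized (Bayesian) covariance: A^-1 XtWX A^-1 would be frequentist;
    # the Bayesian form A^-1 is what mgcv-style intervals use
    Vb = np.linalg.inv(A)

    model = SurfaceModel(
        coefficients=beta, lam=float(lam), edf=edf, chi2=np.nan, p_value=np.nan,
        k=k, x_range=x_range, y_range=y_range, cov_unscaled=Vb,
        centring=centring, separation_warning=separation,
    )
    chi2, p = smooth_term_test(model, X=X)
    return SurfaceModel(
        coefficients=beta, lam=float(lam), edf=edf, chi2=chi2, p_value=p,
        k=k, x_range=x_range, y_range=y_range, cov_unscaled=Vb,
        centring=centring, separation_warning=separation,
    )


def smooth_term_test(model: SurfaceModel, X: np.ndarray | None = None) -> tuple:
    """Wald-type test of the 2-D smooth against the constant model.

    The smooth part of the linear predictor, f = X_s beta_s, is tested
    with the statistic ``f' V_f^{r-} f`` where ``V_f`` is its penalized
    covariance and the pseudo-inverse is truncated at rank
    ``r = min(rank, round(edf of the smooth))``; the reference
    distribution is chi-square with r degrees of freedom.

    Returns ``(chi2, p)``; zero smooth coefficients give (0, 1).
    """
    beta_s = model.coefficients[1:]
    if np.allclose(beta_s, 0.0):
        return 0.0, 1.0
    if X is None:
        raise ValueError("the design matrix of the fit is required")
    Xs = X[:, 1:]
    f = Xs @ beta_s
    Vs = model.cov_unscaled[1:, 1:]
    Vf = Xs @ Vs @ Xs.T
    # rank-truncated pseudo-inverse at the smooth's effective df
    vals, vecs = np.linalg.eigh(Vf)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    edf_smooth = max(model.edf - 1.0, 1.0)
    r = int(min(np.sum(vals > vals[0] * 1e-10), max(np.round(edf_smooth), 1)))
    vi = vecs[:, :r]
    chi2 = float(f @ vi @ np.diag(1.0 / vals[:r]) @ vi.T @ f)
    p = float(stats.chi2.sf(chi2, df=r))
    return chi2, p


def predict_surface(
    model: SurfaceModel,
    grid,
    level: float = 0.95,
) -> pd.DataFrame:
    """Predicted probability surface with confidence bands on a grid.

    ``grid`` is ``(x_edges, y_edges)``; predictions are at cell centres.
    Bands are formed on the link scale from the penalized coefficient
    covariance and mapped through the logistic function, so they always
    contain the point estimate.  Cells outside the data bounding box are
    flagged as extrapolated.

    Returns a tidy frame with columns pc1, pc2, prob, lo, hi, extrapolated.
    """
    x_edges, y_edges = grid
    xc = 0.5 * (np.asarray(x_edges)[:-1] + np.asarray(x_edges)[1:])
    yc = 0.5 * (np.asarray(y_edges)[:-1] + np.asarray(y_edges)[1:])
    XX, YY = np.meshgrid(xc, yc)
    p1, p2 = XX.ravel(), YY.ravel()
    B = model.basis(p1, p2)
    eta = B @ model.coefficients
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, model.cov_unscaled, B), 0.0))
    zq = stats.norm.ppf(0.5 + level / 2.0)
    inv = lambda t: 1.0 / (1.0 + np.exp(-np.clip(t, -500, 500)))
    extrap = (
        (p1 < model.x_range[0]) | (p1 > model.x_range[1])
        | (p2 < model.y_range[0]) | (p2 > model.y_range[1])
    )
    return pd.DataFrame({
        "pc1": p1, "pc2": p2,
        "prob": inv(eta),
        "lo": inv(eta - zq * se),
        "hi": inv(eta + zq * se),
        "extrapolated": extrap,
    })
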
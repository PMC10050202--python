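"""Phylogenetically informed multiple imputation of life-history traits.

Missing trait cells are filled by chained-equations predictive mean
matching (PMM): each incomplete variable is regressed in turn on the other
traits plus phylogenetic eigenvector covariates, and every missing cell
receives the *observed* value of a randomly chosen near neighbour in
predicted-mean space.  Phylogenetic structure enters through the leading
eigenvectors of the double-centred Brownian covariance matrix, the
standard phylogenetic-eigenvector-regression device.

Traits are modelled on the log scale (logit for the two survival
probabilities) and z-scaled inside the chain, then back-transformed; PMM
therefore never produces a value outside the observed range of a trait.

The study design repeats single-chain imputation (m = 1, maxit = 15)
40 times with distinct seeds, giving 40 completed datasets whose spread
carries the imputation uncertainty through the downstream analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import gaussian_kde

from .phylo import PhyloCov
from .synthetic import SURVIVAL_TRAITS

__all__ = [
    "ImputationSet",
    "phylo_eigenvectors",
    "pmm_impute",
    "build_imputation_set",
    "imputation_diagnostics",
    "to_model_scale",
    "from_model_scale",
]

DEFAULT_N_DATASETS = 40
DEFAULT_MAXIT = 15
DEFAULT_DONORS = 5


# ---------------------------------------------------------------------------
# Transforms

def to_model_scale(table: pd.DataFrame) -> pd.DataFrame:
    """Log-transform positive traits, logit-transform survivals."""
    out = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        if col in SURVIVAL_TRAITS:
            with np.errstate(divide="ignore"):
                out[col] = logit(x)
        else:
            with np.errstate(divide="ignore"):
                out[col] = np.log(x)
    return pd.DataFrame(out, index=table.index)


def from_model_scale(table: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`to_model_scale`."""
    out = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        out[col] = expit(x) if col in SURVIVAL_TRAITS else np.exp(x)
    return pd.DataFrame(out, index=table.index)


# ---------------------------------------------------------------------------
# Phylogenetic eigenvector covariates

def phylo_eigenvectors(cov: PhyloCov, k: int) -> np.ndarray:
    """Top-k eigenvectors of the double-centred phylogenetic covariance.

    Double-centring removes the grand trend so the leading eigenvectors
    describe contrasts between clades; they serve as fixed covariates that
    let an ordinary regression borrow strength from relatives.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = cov.n
    if k >= n:
        raise ValueError(f"k must be smaller than the number of tips ({n})")
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ cov.C @ J
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1][:k]
    E = vecs[:, order]
    # deterministic sign: largest-|entry| component positive
    for j in range(E.shape[1]):
        i = np.argmax(np.abs(E[:, j]))
        if E[i, j] < 0:
            E[:, j] = -E[:, j]
    return E


def default_n_eigenvectors(n: int) -> int:
    """Default covariate count: min(15, n/10), at least 1."""
    return max(1, min(15, n // 10))


# ---------------------------------------------------------------------------
# Predictive mean matching

def _bayes_draw_and_fit(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Least-squares fit plus a draw from the approximate posterior.

    Classic PMM (type-1 matching): observed cases are scored with the
    least-squares coefficients, missing cases with a posterior draw, so
    donor matching reflects parameter uncertainty.
    """
    n, p = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    # scaled inverse-chi-square draw for the residual variance
    sigma2 = max(float(resid @ resid) / rng.chisquare(dof), 1e-12)
    cov = sigma2 * np.linalg.inv(XtX)
    beta_star = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    return beta_hat, beta_star


def pmm_impute(
    table: pd.DataFrame,
    covariates: np.ndarray | None = None,
    m: int = 1,
    maxit: int = DEFAULT_MAXIT,
    donors: int = DEFAULT_DONORS,
    seed: int = 0,
) -> pd.DataFrame:
    """Chained-equations PMM imputation of one trait table.

    Parameters
    ----------
    table : DataFrame
        Natural-scale trait table; NaN marks missing cells.
    covariates : array (n, k), optional
        Extra fixed covariates (phylogenetic eigenvectors), aligned to rows.
    m : int
        Completed datasets per chain (kept at 1 in the study design;
        ``m > 1`` returns a list).
    maxit : int
        Fixed number of chained-equation sweeps (no convergence test).
    donors : int
        Donor-pool size for nearest-neighbour matching.

    Returns
    -------
    DataFrame (or list of DataFrames when ``m > 1``)
        Completed table; observed cells are untouched and every imputed
        value is an observed value of the same variable.
    """
    if table.isna().all(axis=0).any():
        bad = [c for c in table.columns if table[c].isna().all()]
        raise ValueError(f"variable(s) with no observed values: {bad}")
    results = []
    for chain in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain]))
        results.append(_pmm_single(table, covariates, maxit, donors, rng))
    return results[0] if m == 1 else results


def _pmm_single(table, covariates, maxit, donors, rng):
    Z = to_model_scale(table)
    M = table.isna()
    cols = list(table.columns)
    data = Z.to_numpy(dtype=float).copy()
    miss = M.to_numpy()
    n = data.shape[0]

    extra = np.empty((n, 0)) if covariates is None else np.asarray(covariates, dtype=float)

    # initial fill: random draws from observed values of the variable
    for j, col in enumerate(cols):
        mj = miss[:, j]
        if mj.any():
            obs = data[~mj, j]
            data[mj, j] = rng.choice(obs, size=mj.sum(), replace=True)

    # visit incomplete variables in order of increasing missingness
    incomplete = [j for j in range(len(cols)) if miss[:, j].any()]
    incomplete.sort(key=lambda j: (miss[:, j].sum(), j))

    col_mean = np.nanmean(np.where(miss, np.nan, data), axis=0)
    col_sd = np.nanstd(np.where(miss, np.nan, data), axis=0)
    col_sd[col_sd == 0] = 1.0

    for _ in range(maxit):
        for j in incomplete:
            mj = miss[:, j]
            others = [k for k in range(len(cols)) if k != j]
            # z-scale predictors with observed-data moments
            P = (data[:, others] - col_mean[others]) / col_sd[others]
            X = np.column_stack([np.ones(n), P, extra])
            y = data[:, j]
            beta_hat, beta_star = _bayes_draw_and_fit(X[~mj], y[~mj], rng)
            pred_obs = X[~mj] @ beta_hat
            pred_mis = X[mj] @ beta_star
            obs_vals = y[~mj]
            d = np.abs(pred_obs[None, :] - pred_mis[:, None])
            k = min(donors, obs_vals.shape[0])
            nearest = np.argpartition(d, kth=k - 1, axis=1)[:, :k]
            pick = nearest[np.arange(nearest.shape[0]), rng.integers(0, k, size=nearest.shape[0])]
            data[mj, j] = obs_vals[pick]

    completed = from_model_scale(pd.DataFrame(data, index=table.index, columns=cols))
    # restore observed cells exactly (round-trip transform noise)
    completed = completed.where(M, table)
    return completed


# ---------------------------------------------------------------------------
# Imputation set

@dataclass(frozen=True)
class ImputationSet:
    """A collection of completed trait tables from repeated imputation."""

    datasets: tuple
    m: int
    maxit: int
    seed: int
    seeds: tuple

    @property
    def n_datasets(self) -> int:
        return len(self.datasets)


def build_imputation_set(
    table: pd.DataFrame,
    covariates: np.ndarray | None = None,
    n_datasets: int = DEFAULT_N_DATASETS,
    m: int = 1,
    maxit: int = DEFAULT_MAXIT,
    donors: int = DEFAULT_DONORS,
    seed: int = 0,
) -> ImputationSet:
    """Run ``n_datasets`` independent single-imputation chains.

    Chain *i* uses seed ``seed + i + 1``; observed cells are identical in
    every completed dataset.
    """
    seeds = tuple(seed + i + 1 for i in range(n_datasets))
    datasets = tuple(
        pmm_impute(table, covariates, m=m, maxit=maxit, donors=donors, seed=s)
        for s in seeds
    )
    return ImputationSet(datasets=datasets, m=m, maxit=maxit, seed=seed, seeds=seeds)


# ---------------------------------------------------------------------------
# Diagnostics

def density_overlap(a: np.ndarray, b: np.ndarray, n_grid: int = 512) -> float:
    """Overlap coefficient of two kernel density estimates, in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.array_equal(np.sort(a), np.sort(b)):
        return 1.0
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    span = hi - lo if hi > lo else 1.0
    grid = np.linspace(lo - 0.1 * span, hi + 0.1 * span, n_grid)
    try:
        fa = gaussian_kde(a)(grid)
        fb = gaussian_kde(b)(grid)
    except np.linalg.LinAlgError:
        return float(np.mean(a == b))
    dx = grid[1] - grid[0]
    return float(np.sum(np.minimum(fa, fb)) * dx)


def procrustes_statistic(ref: np.ndarray, other: np.ndarray) -> float:
    """Procrustes sum-of-squares after optimal translation/rotation/scale.

    Zero for configurations identical up to similarity transform.
    """
    from scipy.spatial import procrustes

    _, _, disparity = procrustes(np.asarray(ref, float), np.asarray(other, float))
    return float(disparity)


def imputation_diagnostics(iset: ImputationSet, original: pd.DataFrame) -> pd.DataFrame:
    """Per-trait overlap of observed-value vs imputed-value densities.

    Compares, on the model (log/logit) scale, the distribution of observed
    values with the pooled distribution of imputed values across all
    datasets.  Traits without missing cells get overlap 1.
    """
    M = original.isna()
    rows = []
    for col in original.columns:
        obs = to_model_scale(original[[col]])[col].dropna().to_numpy()
        if not M[col].any():
            rows.append((col, 0, 1.0))
            continue
        imputed = np.concatenate([
            to_model_scale(ds.loc[M[col], [col]])[col].to_numpy()
            for ds in iset.datasets
        ])
        rows.append((col, int(M[col].sum()), density_overlap(obs, imputed)))
    return pd.DataFrame(rows, columns=["trait", "n_missing", "overlap"]).set_index("trait")
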
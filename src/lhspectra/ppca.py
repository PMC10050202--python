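"""Phylogenetically informed PCA of body-mass-corrected life-history traits.

The six focal traits are log- (logit- for survivals) transformed,
regressed on log body mass by PGLS to strip allometry, and z-scored.  The
pPCA then estimates a joint Pagel's lambda by maximum likelihood, forms
the evolutionary correlation matrix

    E = (X - 1 a')' C(lambda)^-1 (X - 1 a') / (n - 1)

with ``a`` the GLS phylogenetic mean, and eigendecomposes it.  PC1 is the
fast-slow continuum (maximum lifespan loads positively by convention) and
PC2 the reproductive-strategy axis (clutch size positive).

Results from the 40 imputed datasets are pooled after sign/order
alignment of the axes; per-cell spread of the pooled scores carries the
imputation uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .phylo import PhyloCov, _chol_solve, fit_lambda, lambda_transform, pgls_residuals
from .impute import to_model_scale
from .synthetic import FOCAL_TRAITS

__all__ = [
    "PPCAResult",
    "preprocess_traits",
    "ppca_fit",
    "varimax",
    "varimax_kaiser",
    "pool_imputations",
]


@dataclass(frozen=True)
class PPCAResult:
    """Fitted (or pooled) phylogenetic PCA.

    ``loadings`` are trait x component eigenvectors of the evolutionary
    correlation matrix, ``scores`` the species projections, and
    ``var_explained`` the eigenvalue fractions (summing to 1 over all
    components).  ``lambda_hat`` is the jointly estimated signal.
    """

    loadings: pd.DataFrame
    scores: pd.DataFrame
    eigenvalues: np.ndarray
    var_explained: np.ndarray
    lambda_hat: float
    n_retained: int
    rotated: bool = False
    score_se: pd.DataFrame | None = None
    loading_se: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Preprocessing

def preprocess_traits(
    table: pd.DataFrame,
    cov: PhyloCov,
    traits=FOCAL_TRAITS,
    mass_col: str = "mass",
    lambdas: dict | None = None,
) -> pd.DataFrame:
    """Log/logit -> PGLS residual on log mass -> z-score, per focal trait.

    ``lambdas`` optionally fixes the signal used in each trait's
    allometric regression; by default each trait's own ML lambda estimate
    is used.  The input must be complete (post-imputation).

    Raises
    ------
    ValueError
        On missing cells or non-positive trait values.
    """
    sub = table[list(traits) + [mass_col]]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"preprocess requires complete data; NaN in {bad}")
    bad_cells = [
        (sp, t)
        for t in list(traits) + [mass_col]
        for sp in table.index[table[t] <= 0]
    ]
    if bad_cells:
        raise ValueError(f"non-positive trait values at {bad_cells[:10]}")

    covo = cov.reorder(list(table.index)) if tuple(table.index) != cov.labels else cov
    Z = to_model_scale(table[list(traits)])
    log_mass = np.log(table[mass_col].to_numpy(dtype=float))

    out = {}
    for t in traits:
        y = Z[t].to_numpy()
        lam = (lambdas or {}).get(t)
        if lam is None:
            fit = fit_lambda(y, covo)
            lam = 0.0 if fit.degenerate else fit.lambda_hat
        r = pgls_residuals(y, log_mass, covo, lam=lam)
        sd = r.std()
        if sd < 1e-12:
            raise ValueError(f"trait {t} is degenerate after mass correction")
        out[t] = (r - r.mean()) / sd
    X = pd.DataFrame(out, index=table.index)
    X.index.name = "species"
    return X


# ---------------------------------------------------------------------------
# pPCA

def _matrix_profile_loglik(lam: float, X: np.ndarray, cov: PhyloCov):
    """Profile log-likelihood of lambda for the matrix-normal trait model."""
    n, p = X.shape
    V = lambda_transform(cov, lam).C
    ones = np.ones((n, 1))
    B = np.hstack([X, ones])
    VinvB, logdetV = _chol_solve(V, B)
    VinvX, Vinv1 = VinvB[:, :p], VinvB[:, p:]
    a = (ones.T @ VinvX) / (ones.T @ Vinv1)          # GLS mean, 1 x p
    Xc = X - ones @ a
    VinvXc = VinvX - Vinv1 @ a
    E_ml = Xc.T @ VinvXc / n
    sign, logdetE = np.linalg.slogdet(E_ml)
    if sign <= 0:
        return -np.inf, a.ravel(), E_ml
    ll = -0.5 * (n * p * np.log(2 * np.pi) + p * logdetV + n * logdetE + n * p)
    return ll, a.ravel(), E_ml


def ppca_fit(X: pd.DataFrame, cov: PhyloCov) -> PPCAResult:
    """Phylogenetic PCA with jointly ML-estimated Pagel's lambda.

    The evolutionary covariance is converted to correlation scale before
    eigendecomposition, so the eigenvalues sum to the number of traits;
    scores are the projections of the GLS-centred, scaled data onto the
    eigenvectors.  Deterministic given inputs.
    """
    traits = list(X.columns)
    species = list(X.index)
    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    if n < p + 1:
        raise ValueError("need more species than traits")
    covo = cov.reorder(species) if tuple(species) != cov.labels else cov

    res = optimize.minimize_scalar(
        lambda lam: -_matrix_profile_loglik(lam, Xm, covo)[0],
        bounds=(0.0, 1.0), method="bounded", options={"xatol": 1e-6},
    )
    lam_hat = float(np.clip(res.x, 0, 1))
    ll_hat = -res.fun
    for edge in (0.0, 1.0):
        ll_edge = _matrix_profile_loglik(edge, Xm, covo)[0]
        if ll_edge > ll_hat:
            lam_hat, ll_hat = edge, ll_edge

    _, a, E_ml = _matrix_profile_loglik(lam_hat, Xm, covo)
    E = E_ml * n / (n - 1)  # unbiased-style scaling for reporting
    d = np.sqrt(np.diag(E))
    if np.any(d <= 0):
        raise ValueError("singular evolutionary covariance")
    R = E / np.outer(d, d)
    vals, vecs = np.linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]

    Xc = (Xm - a) / d
    scores = Xc @ vecs

    comp = [f"PC{i + 1}" for i in range(p)]
    result = PPCAResult(
        loadings=pd.DataFrame(vecs, index=traits, columns=comp),
        scores=pd.DataFrame(scores, index=species, columns=comp),
        eigenvalues=vals,
        var_explained=vals / vals.sum(),
        lambda_hat=lam_hat,
        n_retained=int(np.sum(vals > 1)),
    )
    return orient_axes(result)


def orient_axes(result: PPCAResult, conventions=(("ML", "PC1"), ("CS", "PC2"))) -> PPCAResult:
    """Fix the arbitrary sign of each axis by a loading convention.

    Defaults: maximum lifespan loads positively on PC1 (slow species to
    the right) and clutch size positively on PC2.
    """
    L = result.loadings.copy()
    S = result.scores.copy()
    for trait, comp in conventions:
        if trait in L.index and comp in L.columns and L.loc[trait, comp] < 0:
            L[comp] = -L[comp]
            S[comp] = -S[comp]
    return replace(result, loadings=L, scores=S)


# ---------------------------------------------------------------------------
# Varimax + Kaiser

def varimax(L: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Orthogonal varimax rotation matrix for a loading matrix."""
    p, k = L.shape
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        B = L @ R
        U, s, Vt = np.linalg.svd(L.T @ (B ** 3 - B @ np.diag(np.sum(B ** 2, axis=0)) / p))
        R = U @ Vt
        var_new = np.sum(s)
        if var_new - var_old < tol:
            break
        var_old = var_new
    return R


def varimax_criterion(L: np.ndarray) -> float:
    """The varimax objective: sum of per-column variances of squared loadings."""
    sq = L ** 2
    return float(np.sum(sq.var(axis=0)))


def varimax_kaiser(result: PPCAResult) -> PPCAResult:
    """Varimax-rotate the Kaiser-retained components (eigenvalue > 1).

    Only the retained block is rotated; scores for that block are
    recomputed in the rotated basis.  Raises if no component passes the
    Kaiser criterion.
    """
    keep = int(np.sum(result.eigenvalues > 1))
    if keep == 0:
        raise ValueError("no component has eigenvalue > 1")
    comps = list(result.loadings.columns[:keep])
    L = result.loadings[comps].to_numpy()
    R = varimax(L)
    Lr = L @ R
    loadings = result.loadings.copy()
    loadings.loc[:, comps] = Lr
    scores = result.scores.copy()
    scores.loc[:, comps] = result.scores[comps].to_numpy() @ R
    rotated = replace(
        result, loadings=loadings, scores=scores, n_retained=keep, rotated=True
    )
    return orient_axes(rotated)


# ---------------------------------------------------------------------------
# Pooling over imputations

def _align_to(ref: PPCAResult, other: PPCAResult, tie_tol: float = 1e-6):
    """Match axes of ``other`` to ``ref`` by absolute loading correlation.

    Greedy assignment over components; sign is flipped when the matched
    correlation is negative.  Near-ties resolve to the earlier original
    axis for determinism.
    """
    Lr = ref.loadings.to_numpy()
    Lo = other.loadings.to_numpy()
    k = Lr.shape[1]
    corr = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            a, b = Lr[:, i], Lo[:, j]
            denom = np.linalg.norm(a) * np.linalg.norm(b)
            corr[i, j] = (a @ b) / denom if denom > 0 else 0.0
    perm = np.full(k, -1)
    signs = np.ones(k)
    used = set()
    for i in range(k):
        cands = [(abs(corr[i, j]), -j) for j in range(k) if j not in used]
        best = max(cands)
        # deterministic tie-break: earliest original axis among near-ties
        ties = [j for j in range(k) if j not in used and abs(abs(corr[i, j]) - best[0]) < tie_tol]
        j = min(ties)
        perm[i] = j
        signs[i] = 1.0 if corr[i, j] >= 0 else -1.0
        used.add(j)
    return perm, signs


def pool_imputations(results) -> tuple:
    """Pool pPCA results across imputed datasets.

    Axes of every result are aligned (order and sign) to the first; the
    pooled loadings/scores are element-wise means and the standard error
    is the element-wise SD / sqrt(n_results).

    Returns
    -------
    (PPCAResult, DataFrame)
        The pooled result and the functional space (species, pc1, pc2,
        per-axis pooled SE).
    """
    results = list(results)
    if not results:
        raise ValueError("no results to pool")
    ref = results[0]
    traits = list(ref.loadings.index)
    species = list(ref.scores.index)
    comps = list(ref.loadings.columns)

    Ls, Ss, Vs, lams = [], [], [], []
    for r in results:
        if list(r.loadings.index) != traits or list(r.scores.index) != species:
            raise ValueError("results must share trait and species sets")
        perm, signs = _align_to(ref, r)
        Ls.append(r.loadings.to_numpy()[:, perm] * signs)
        Ss.append(r.scores.to_numpy()[:, perm] * signs)
        Vs.append(np.asarray(r.var_explained)[perm])
        lams.append(r.lambda_hat)
    Ls, Ss, Vs = np.array(Ls), np.array(Ss), np.array(Vs)
    nrep = len(results)

    pooled_var = Vs.mean(axis=0)
    # re-sort by pooled variance: axis order can drift across imputations
    order = np.argsort(pooled_var)[::-1]
    pooled_var = pooled_var[order]
    Ls, Ss = Ls[:, :, order], Ss[:, :, order]
    pooled = PPCAResult(
        loadings=pd.DataFrame(Ls.mean(axis=0), index=traits, columns=comps),
        scores=pd.DataFrame(Ss.mean(axis=0), index=species, columns=comps),
        eigenvalues=pooled_var * len(traits),
        var_explained=pooled_var,
        lambda_hat=float(np.mean(lams)),
        n_retained=ref.n_retained,
        rotated=ref.rotated,
        score_se=pd.DataFrame(Ss.std(axis=0, ddof=0) / np.sqrt(nrep),
                              index=species, columns=comps),
        loading_se=pd.DataFrame(Ls.std(axis=0, ddof=0) / np.sqrt(nrep),
                                index=traits, columns=comps),
    )
    pooled = orient_axes(pooled)
    space = pd.DataFrame({
        "pc1": pooled.scores["PC1"],
        "pc2": pooled.scores["PC2"],
        "pc1_se": pooled.score_se["PC1"],
        "pc2_se": pooled.score_se["PC2"],
    })
    space.index.name = "species"
    return pooled, space
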
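"""Phylogenetic comparative primitives.

Builds the Brownian-motion phylogenetic covariance matrix from a tree,
estimates Pagel's lambda by maximum likelihood, computes phylogenetic
generalized least squares (PGLS) residuals, and runs the Kruskal-Wallis
test used to check whether trait missingness is associated with threat
status.

The covariance convention is the standard one for Brownian motion on a
rooted tree: ``C[i, j]`` is the depth (root-to-node distance) of the most
recent common ancestor of tips *i* and *j*, and ``C[i, i]`` is the
root-to-tip distance.  Pagel's lambda multiplies the off-diagonal entries,
so lambda = 0 removes all phylogenetic structure and lambda = 1 is the
plain Brownian expectation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import dendropy
import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloCov",
    "read_newick",
    "write_newick",
    "phylo_vcv",
    "lambda_transform",
    "fit_lambda",
    "LambdaFit",
    "pgls_fit",
    "pgls_residuals",
    "kruskal_missingness_test",
]

#: jitter added to the covariance diagonal when a Cholesky factorisation
#: fails (e.g. tips separated by zero-length branches)
CHOL_JITTER = 1e-10


@dataclass(frozen=True)
class PhyloCov:
    """Phylogenetic covariance matrix with its signal parameter.

    Attributes
    ----------
    C : ndarray, shape (n, n)
        Shared branch-length matrix (units of tree depth).
    labels : tuple of str
        Tip labels, one per row/column of ``C``.
    lam : float
        Pagel's lambda already applied to the off-diagonals of ``C``.
    """

    C: np.ndarray
    labels: tuple
    lam: float = 1.0

    def __post_init__(self):
        C = np.asarray(self.C, dtype=float)
        if C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C must be a square matrix")
        if len(self.labels) != C.shape[0]:
            raise ValueError("labels must match the dimension of C")
        if not np.allclose(C, C.T, atol=1e-8):
            raise ValueError("C must be symmetric")
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return self.C.shape[0]

    def reorder(self, labels) -> "PhyloCov":
        """Return a copy with rows/columns permuted to ``labels``."""
        idx = [self.labels.index(l) for l in labels]
        return replace(self, C=self.C[np.ix_(idx, idx)], labels=tuple(labels))


# ---------------------------------------------------------------------------
# Newick I/O

def read_newick(source) -> dendropy.Tree:
    """Read a rooted tree from a Newick file path or string.

    Quoted labels and zero-length branches are accepted; underscores in
    unquoted labels are preserved (not converted to spaces).
    """
    kwargs = dict(
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    if hasattr(source, "read"):
        return dendropy.Tree.get(file=source, **kwargs)
    text = str(source)
    if "(" in text and ";" in text:
        return dendropy.Tree.get(data=text, **kwargs)
    return dendropy.Tree.get(path=text, **kwargs)


def write_newick(tree: dendropy.Tree, path=None) -> str:
    """Serialise a tree to Newick; labels round-trip unmodified."""
    text = tree.as_string(schema="newick", unquoted_underscores=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Covariance construction

def phylo_vcv(tree: dendropy.Tree) -> PhyloCov:
    """Brownian-motion covariance matrix of a rooted tree.

    ``C[i, j]`` is the depth of the MRCA of tips *i* and *j* measured from
    the root; the diagonal holds root-to-tip distances.  The root edge (if
    any) is ignored, as it contributes equally to every entry only when the
    process starts below the root.

    Raises
    ------
    ValueError
        If any branch length is negative or non-finite.
    """
    if isinstance(tree, str):
        tree = read_newick(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels in tree")
    n = len(labels)

    # node depths from the root (root edge excluded)
    depth = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            bl = node.edge.length if node.edge.length is not None else 0.0
            if not np.isfinite(bl):
                raise ValueError("non-finite branch length in tree")
            if bl < 0:
                raise ValueError(f"negative branch length ({bl}) in tree")
            depth[node] = depth[node.parent_node] + bl

    leaf_index = {lf: i for i, lf in enumerate(leaves)}
    C = np.zeros((n, n))
    for i, lf in enumerate(leaves):
        C[i, i] = depth[lf]
    # post-order sweep: at each internal node, tip pairs drawn from two
    # different child subtrees have that node as their MRCA
    tips_below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips_below[node] = [leaf_index[node]]
            continue
        groups = [tips_below.pop(ch) for ch in node.child_nodes()]
        d = depth[node]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia = np.asarray(groups[a])
                ib = np.asarray(groups[b])
                C[np.ix_(ia, ib)] = d
                C[np.ix_(ib, ia)] = d
        tips_below[node] = [i for g in groups for i in g]
    return PhyloCov(C=C, labels=tuple(labels), lam=1.0)


def lambda_transform(cov: PhyloCov, lam: float) -> PhyloCov:
    """Apply Pagel's lambda: scale off-diagonal entries, keep the diagonal."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    C = cov.C * lam
    np.fill_diagonal(C, np.diag(cov.C))
    return replace(cov, C=C, lam=cov.lam * lam if cov.lam != 1.0 else lam)


def _chol_solve(V: np.ndarray, B: np.ndarray):
    """Cholesky solve with a logged jitter fallback for PSD failures.

    Returns ``(V^-1 B, log|V|)``.
    """
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        # first failure per session at WARNING, the rest at DEBUG
        level = logging.DEBUG if getattr(_chol_solve, "_warned", False) else logging.WARNING
        logger.log(level, "covariance not PD; adding jitter %.1e to diagonal", CHOL_JITTER)
        _chol_solve._warned = True
        L = np.linalg.cholesky(V + CHOL_JITTER * np.mean(np.diag(V)) * np.eye(V.shape[0]))
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    X = np.linalg.solve(L, B)
    return np.linalg.solve(L.T, X), logdet


# ---------------------------------------------------------------------------
# Pagel's lambda

@dataclass(frozen=True)
class LambdaFit:
    """Result of a maximum-likelihood Pagel's lambda fit."""

    lambda_hat: float
    loglik: float
    se: float
    sigma2: float = np.nan
    mu: float = np.nan
    degenerate: bool = False


def _profile_loglik(lam: float, y: np.ndarray, cov: PhyloCov) -> float:
    """Profile log-likelihood of lambda with mu and sigma^2 profiled out."""
    n = y.shape[0]
    V = lambda_transform(cov, lam).C
    ones = np.ones(n)
    B = np.column_stack([y, ones])
    VinvB, logdet = _chol_solve(V, B)
    Vinv_y, Vinv_1 = VinvB[:, 0], VinvB[:, 1]
    mu = (ones @ Vinv_y) / (ones @ Vinv_1)
    r = y - mu
    # quadratic form r' V^-1 r without an extra solve
    q = r @ Vinv_y - mu * (r @ Vinv_1)
    sigma2 = max(q / n, 1e-300)
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def fit_lambda(y, cov: PhyloCov, tol: float = 1e-6) -> LambdaFit:
    """Maximum-likelihood estimate of Pagel's lambda for one trait.

    The likelihood is multivariate normal with mean ``mu * 1`` and
    covariance ``sigma2 * C(lambda)``; ``mu`` and ``sigma2`` are profiled
    out and lambda is optimised on [0, 1] by bounded Brent search.  The
    standard error comes from the curvature of the profile log-likelihood.

    A constant trait vector has no information about lambda; the result is
    then flagged ``degenerate`` with ``lambda_hat = nan``.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 4:
        raise ValueError("need at least 4 tips to estimate lambda")
    if n != cov.n:
        raise ValueError("trait vector and covariance dimension mismatch")
    if np.ptp(y) == 0:
        return LambdaFit(np.nan, np.nan, np.nan, degenerate=True)

    res = optimize.minimize_scalar(
        lambda lam: -_profile_loglik(lam, y, cov),
        bounds=(0.0, 1.0), method="bounded",
        options={"xatol": tol},
    )
    lam_hat = float(np.clip(res.x, 0.0, 1.0))
    ll_hat = -res.fun
    # boundary-aware check: the interior optimum can lose to an endpoint
    for edge in (0.0, 1.0):
        ll_edge = _profile_loglik(edge, y, cov)
        if ll_edge > ll_hat:
            lam_hat, ll_hat = edge, ll_edge

    # curvature-based SE (one-sided steps at the boundary)
    h = 1e-4
    lo, hi = max(lam_hat - h, 0.0), min(lam_hat + h, 1.0)
    f0 = _profile_loglik(lam_hat, y, cov)
    fl = _profile_loglik(lo, y, cov)
    fh = _profile_loglik(hi, y, cov)
    # generalised second difference valid for unequal steps
    d1, d2 = lam_hat - lo, hi - lam_hat
    if d1 > 0 and d2 > 0:
        curv = 2.0 * (fl * d2 + fh * d1 - f0 * (d1 + d2)) / (d1 * d2 * (d1 + d2))
    else:
        step = max(d1, d2)
        mid = lam_hat - step if d1 > 0 else lam_hat + step
        f2 = _profile_loglik(2 * mid - lam_hat if 0 <= 2 * mid - lam_hat <= 1 else mid, y, cov)
        curv = (f2 - 2 * fl if d1 > 0 else f2 - 2 * fh) + f0
        curv /= step ** 2
    se = float(1.0 / np.sqrt(-curv)) if curv < 0 else np.inf

    # recover profiled nuisance parameters at the optimum
    V = lambda_transform(cov, lam_hat).C
    ones = np.ones(n)
    VinvB, _ = _chol_solve(V, np.column_stack([y, ones]))
    mu = (ones @ VinvB[:, 0]) / (ones @ VinvB[:, 1])
    r = y - mu
    sigma2 = (r @ VinvB[:, 0] - mu * (r @ VinvB[:, 1])) / n
    return LambdaFit(lam_hat, float(ll_hat), se, float(sigma2), float(mu))


# ---------------------------------------------------------------------------
# PGLS

def pgls_fit(y, X, cov: PhyloCov, lam: float = 1.0):
    """Generalized least squares fit of ``y`` on ``[1, X]`` under C(lambda).

    Returns ``(beta, residuals)`` where residuals are ``y - X beta`` (raw
    response-scale residuals, the quantity used for body-mass correction).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.shape[0]
    design = np.column_stack([np.ones(n), X])
    for j in range(1, design.shape[1]):
        if np.ptp(design[:, j]) == 0:
            raise ValueError(f"singular design: covariate {j - 1} is constant")
    V = lambda_transform(cov, lam).C if lam != cov.lam else cov.C
    VinvB, _ = _chol_solve(V, np.column_stack([design, y]))
    Vinv_X, Vinv_y = VinvB[:, :-1], VinvB[:, -1]
    XtVinvX = design.T @ Vinv_X
    beta = np.linalg.solve(XtVinvX, design.T @ Vinv_y)
    return beta, y - design @ beta


def pgls_residuals(y, x, cov: PhyloCov, lam: float = 1.0) -> np.ndarray:
    """Residuals of a phylogenetic regression of ``y`` on a single covariate."""
    _, resid = pgls_fit(y, x, cov, lam)
    return resid


# ---------------------------------------------------------------------------
# Missingness association

def kruskal_missingness_test(missing_counts, groups):
    """Kruskal-Wallis test of per-species missing-trait counts across groups.

    Parameters
    ----------
    missing_counts : sequence of int
        Number of missing trait cells per species.
    groups : sequence
        Group label per species (e.g. threatened / non-threatened / DD).

    Returns
    -------
    (H, p, df) : tuple
        Tie-corrected H statistic, chi-square p-value, degrees of freedom.
    """
    missing_counts = np.asarray(missing_counts, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups for a Kruskal-Wallis test")
    samples = [missing_counts[groups == g] for g in levels]
    H, p = stats.kruskal(*samples)
    return float(H), float(p), len(levels) - 1
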
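"""Phylogenetic comparative statistics from first principles.

Trait evolution is modeled as Brownian motion (BM) along a rooted tree with
branch lengths, inducing a covariance between tips equal to their shared
root-to-ancestor path length.  Pagel's lambda scales the off-diagonal
covariance, measuring phylogenetic signal (lambda = 0: star-like
independence; lambda = 1: full BM), and is estimated by maximizing the
Gaussian log-likelihood.  On that covariance are built:

* PGLS - generalized least squares regression with lambda-scaled BM errors;
* phylogenetic ANOVA - the observed one-way F statistic referred to a null
  distribution of F values from BM simulations on the tree with group labels
  held fixed;
* PRMA - reduced major axis (standardized major axis) regression on
  phylogenetically whitened variables;
* plain Pearson correlation tests for the non-phylogenetic analyses.

Trees are dendropy objects; tip trait values may be passed as arrays in tip
order or as pandas objects indexed by tip label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "NewickParseError",
    "PglsFit",
    "read_newick",
    "write_newick",
    "tip_labels",
    "bm_covariance",
    "simulate_bm",
    "pgls_fit",
    "phylo_anova",
    "prma_fit",
    "correlation_test",
    "maybe_log_transform",
]


class NewickParseError(ValueError):
    """The newick string could not be parsed."""


def read_newick(text: str) -> dendropy.Tree:
    """Parse a newick string (with branch lengths) into a rooted tree."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise NewickParseError(f"malformed newick: {exc}") from exc
    if len(tree.leaf_nodes()) == 0:
        raise NewickParseError("newick contains no tips")
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise NewickParseError("tip labels are not unique")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def tip_labels(tree: dendropy.Tree) -> list[str]:
    """Tip labels in stable (leaf-iteration) order."""
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def _tip_depths_and_mrca(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Matrix of shared root-to-MRCA path lengths (diag = tip depths)."""
    labels = tip_labels(tree)
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    # postorder accumulation: each node contributes its edge length to the
    # shared path of every pair of tips descending from it
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        node.depth = (0.0 if parent is None else parent.depth) + (
            node.edge.length or 0.0
        )
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node.tip_set = [idx[node.taxon.label]]
        else:
            children = [c.tip_set for c in node.child_nodes()]
            # pairs of tips whose MRCA is exactly this node
            for i, a in enumerate(children):
                for b in children[i + 1 :]:
                    for ta in a:
                        V[ta, b] = node.depth
                        V[b, ta] = node.depth
            node.tip_set = [t for c in children for t in c]
    for lf in tree.leaf_node_iter():
        i = idx[lf.taxon.label]
        V[i, i] = lf.depth
    return labels, V


def bm_covariance(
    tree: dendropy.Tree, lam: float = 1.0
) -> tuple[list[str], np.ndarray]:
    """Brownian covariance with Pagel's lambda applied to off-diagonals.

    V[i, j] = lam * (shared root-to-MRCA path length) for i != j;
    V[i, i] = root-to-tip depth of tip i (untransformed).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    labels, V = _tip_depths_and_mrca(tree)
    return labels, _apply_lambda(V, lam)


def _apply_lambda(V0: np.ndarray, lam: float) -> np.ndarray:
    d = np.diag(V0).copy()
    V = V0 * lam
    np.fill_diagonal(V, d)
    return V


def simulate_bm(
    tree: dendropy.Tree,
    rate: float = 1.0,
    rng: np.random.Generator | int | None = None,
    n_reps: int = 1,
    root_state: float = 0.0,
) -> tuple[list[str], np.ndarray]:
    """Simulate BM tip states; returns (labels, n_tips x n_reps matrix)."""
    if rate <= 0:
        raise ValueError("BM rate must be > 0")
    rng = np.random.default_rng(rng)
    labels, V = bm_covariance(tree, 1.0)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(labels)))
    z = rng.standard_normal((len(labels), n_reps))
    return labels, root_state + math.sqrt(rate) * (L @ z)


def _align(values, labels: list[str]) -> np.ndarray:
    """Align a Series/DataFrame by tip label, or pass arrays through."""
    if isinstance(values, (pd.Series, pd.DataFrame)):
        missing = [l for l in labels if l not in values.index]
        if missing:
            raise KeyError(f"trait data missing for tips: {missing[:5]}...")
        return values.loc[labels].to_numpy(dtype=float)
    arr = np.asarray(values, dtype=float)
    if arr.shape[0] != len(labels):
        raise ValueError(
            f"{arr.shape[0]} values for {len(labels)} tips; pass data in tip "
            "order or as a pandas object indexed by tip label"
        )
    return arr


# ---------------------------------------------------------------------------
# PGLS with ML Pagel's lambda
# ---------------------------------------------------------------------------

@dataclass
class PglsFit:
    """Coefficients and ML lambda of a phylogenetic GLS regression."""

    coefficients: np.ndarray
    se: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    lam: float
    log_likelihood: float
    r_squared: float
    n: int
    profile: tuple[np.ndarray, np.ndarray] | None = None  # (lambdas, loglik)


def _gls_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray):
    """Profile log-likelihood of a GLS fit (sigma^2 maximized out)."""
    from scipy.linalg import solve_triangular

    n = y.shape[0]
    L = np.linalg.cholesky(V)
    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    ll = -0.5 * (n * math.log(2.0 * math.pi * sigma2) + n + logdet)
    return ll, beta, rss, Xw, yw


def _golden_max(f, lo: float, hi: float, tol: float = 1e-6) -> float:
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while abs(b - a) > tol:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def pgls_fit(y, X, tree: dendropy.Tree, lam="ML") -> PglsFit:
    """Phylogenetic GLS regression of y on X (intercept added).

    ``lam`` is a fixed value in [0, 1] or ``"ML"``: maximum-likelihood
    estimation on a 201-point grid over [0, 1] refined by golden-section
    search, favouring interior maxima over boundary ones when the
    log-likelihood difference is below 1e-6.  Coefficient p-values use
    t statistics with n - k degrees of freedom.
    """
    labels, V0 = _tip_depths_and_mrca(tree)
    yv = _align(y, labels)
    Xv = _align(X, labels)
    if Xv.ndim == 1:
        Xv = Xv[:, None]
    n = yv.shape[0]
    Xd = np.column_stack([np.ones(n), Xv])
    k = Xd.shape[1]
    if np.linalg.matrix_rank(Xd) < k:
        raise np.linalg.LinAlgError("design matrix is rank deficient")

    def ll_at(l: float) -> float:
        return _gls_loglik(yv, Xd, _apply_lambda(V0, l))[0]

    profile = None
    if lam == "ML":
        grid = np.linspace(0.0, 1.0, 201)
        lls = np.array([ll_at(l) for l in grid])
        i = int(np.argmax(lls))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        refined = _golden_max(ll_at, lo, hi) if hi > lo else grid[i]
        # the boundary values must never beat the reported maximum; break
        # near-ties (< 1e-6 log-likelihood) in favour of interior values
        candidates = [(ll_at(l), l) for l in (refined, float(grid[i]), 0.0, 1.0)]
        best_ll = max(c[0] for c in candidates)
        interior = [c for c in candidates if 0.0 < c[1] < 1.0 and best_ll - c[0] < 1e-6]
        lam_hat = max(interior)[1] if interior else max(candidates)[1]
        profile = (grid, lls)
    else:
        lam_hat = float(lam)
        if not 0.0 <= lam_hat <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {lam_hat}")

    V = _apply_lambda(V0, lam_hat)
    ll, beta, rss, Xw, yw = _gls_loglik(yv, Xd, V)
    dof = n - k
    sigma2 = rss / dof
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    t_vals = beta / se
    p_vals = 2.0 * stats.t.sf(np.abs(t_vals), dof)
    # GLS R^2 against the phylogenetic intercept-only model
    ones = np.ones((n, 1))
    _, _, tss, _, _ = _gls_loglik(yv, ones, V)
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    return PglsFit(
        coefficients=beta,
        se=se,
        t_values=t_vals,
        p_values=p_vals,
        lam=float(lam_hat),
        log_likelihood=ll,
        r_squared=float(r2),
        n=n,
        profile=profile,
    )


# ---------------------------------------------------------------------------
# simulation-based phylogenetic ANOVA
# ---------------------------------------------------------------------------

def _anova_F(y: np.ndarray, masks: list[np.ndarray]) -> np.ndarray:
    """One-way ANOVA F for each column of y (n x r matrix)."""
    y = np.atleast_2d(y.T).T
    n, _ = y.shape
    k = len(masks)
    grand = y.mean(axis=0)
    ssb = np.zeros(y.shape[1])
    ssw = np.zeros(y.shape[1])
    for m in masks:
        g = y[m]
        gm = g.mean(axis=0)
        ssb += m.sum() * (gm - grand) ** 2
        ssw += ((g - gm) ** 2).sum(axis=0)
    return (ssb / (k - 1)) / (ssw / (n - k))


def phylo_anova(
    trait,
    groups,
    tree: dendropy.Tree,
    n_sim: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Phylogenetic ANOVA: observed F against a BM-simulation null.

    ``groups`` are per-tip labels (aligned like ``trait``).  The BM rate is
    estimated from the data (GLS residual rate under lambda = 1), ``n_sim``
    trait sets are simulated on the tree with group labels held fixed, and
    p = (1 + #{F_sim >= F_obs}) / (n_sim + 1).
    """
    labels, V = bm_covariance(tree, 1.0)
    yv = _align(trait, labels)
    if isinstance(groups, (pd.Series, pd.DataFrame)):
        gv = groups.loc[labels].to_numpy()
    else:
        gv = np.asarray(groups)
        if gv.shape[0] != len(labels):
            raise ValueError("group labels must align with tree tips")
    uniq = pd.unique(gv)
    if len(uniq) < 2:
        raise ValueError("phylogenetic ANOVA needs at least 2 groups")
    masks = [gv == u for u in uniq]
    if any(m.sum() < 1 for m in masks):
        raise ValueError("every group must be non-empty")
    if np.ptp(yv) == 0:
        raise ValueError("trait is constant: F undefined")

    F_obs = float(_anova_F(yv, masks)[0])

    # BM rate from the data: GLS mean under full BM, quadratic-form rate
    n = len(yv)
    Vinv_y = np.linalg.solve(V, yv)
    Vinv_1 = np.linalg.solve(V, np.ones(n))
    mu = float(np.ones(n) @ Vinv_y / (np.ones(n) @ Vinv_1))
    r = yv - mu
    rate = float(r @ np.linalg.solve(V, r)) / n
    rate = max(rate, 1e-12)

    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(V + 1e-12 * np.eye(n))
    sims = math.sqrt(rate) * (L @ rng.standard_normal((n, n_sim)))
    F_sim = _anova_F(sims, masks)
    p = (1.0 + np.sum(F_sim >= F_obs)) / (n_sim + 1.0)
    return {"F_obs": F_obs, "p_phylo": float(p), "n_sim": n_sim, "rate": rate}


# ---------------------------------------------------------------------------
# phylogenetic reduced major axis
# ---------------------------------------------------------------------------

def prma_fit(x, y, tree: dendropy.Tree, lam: float = 1.0) -> dict:
    """Reduced major axis regression on phylogenetically whitened variables.

    Both variables are centered on their GLS (phylogenetic) means and
    rotated by the inverse Cholesky factor of V(lambda); the RMA slope is
    sign(r) * SD(y*) / SD(x*) and the intercept passes through the GLS
    means.  Returns ``{"slope", "intercept", "r"}``.
    """
    from scipy.linalg import solve_triangular

    labels, V = bm_covariance(tree, lam)
    xv = _align(x, labels)
    yv = _align(y, labels)
    n = len(labels)
    L = np.linalg.cholesky(V)
    ones_w = solve_triangular(L, np.ones(n), lower=True)
    xw = solve_triangular(L, xv, lower=True)
    yw = solve_triangular(L, yv, lower=True)
    mu_x = float(ones_w @ xw / (ones_w @ ones_w))
    mu_y = float(ones_w @ yw / (ones_w @ ones_w))
    xc = xw - mu_x * ones_w
    yc = yw - mu_y * ones_w
    sx = float(np.sqrt(xc @ xc))
    sy = float(np.sqrt(yc @ yc))
    if sx == 0:
        raise ValueError("zero variance in x after transformation")
    if sy == 0:
        raise ValueError("zero variance in y after transformation")
    r = float(xc @ yc / (sx * sy))
    slope = math.copysign(sy / sx, r if r != 0 else 1.0)
    intercept = mu_y - slope * mu_x
    return {"slope": slope, "intercept": intercept, "r": r}


def correlation_test(x, y) -> dict:
    """Pearson correlation r with two-sided p from the t distribution."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(xv, yv)
    p = float(res.pvalue)
    if p == 0.0:
        p = np.nextafter(0.0, 1.0)
    return {"r": float(res.statistic), "p": p}


def maybe_log_transform(values: np.ndarray, enabled: bool = True) -> tuple[np.ndarray, bool]:
    """Log-transform strictly positive data spanning > one order of magnitude.

    Mirrors the power-law character of hydraulic trait scaling; returns the
    (possibly transformed) array and whether the transform was applied.
    """
    arr = np.asarray(values, dtype=float)
    if (
        enabled
        and np.all(arr > 0)
        and arr.max() / arr.min() > 10.0
    ):
        return np.log(arr), True
    return arr, False
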
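"""Phylogenetic comparative statistics.

Builds the Brownian-motion tip covariance matrix from a rooted tree,
estimates Pagel's λ by maximum likelihood with likelihood-ratio tests
against λ=0 and λ=1 (both referred to χ²(1)), fits phylogenetic
generalized least squares regressions, and screens predictors for
collinearity by pairwise correlation and (generalized) variance inflation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = [
    "PhyloCovariance",
    "LambdaFit",
    "PGLSFit",
    "vcv",
    "lambda_transform",
    "fit_lambda",
    "pgls",
    "collinearity_screen",
    "ScreenReport",
]


@dataclass
class PhyloCovariance:
    """Tip-tip Brownian covariance: C[i, j] = depth of the MRCA of tips i, j.

    ``depth_scale`` is the constant C was divided by when ``normalize=True``
    (the maximum root-to-tip depth), so variance components are comparable
    across trees.
    """

    matrix: np.ndarray
    taxa: list[str]
    depth_scale: float = 1.0

    def reorder(self, taxa: Sequence[str]) -> "PhyloCovariance":
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(taxa),
                               self.depth_scale)

    def correlation(self) -> np.ndarray:
        d = np.sqrt(np.diag(self.matrix))
        return self.matrix / np.outer(d, d)


def vcv(tree: dendropy.Tree, taxa: Optional[Sequence[str]] = None,
        normalize: bool = False) -> PhyloCovariance:
    """Shared-path covariance matrix of a rooted tree's tips.

    C(i, j) is the root-to-MRCA depth of tips i and j; the diagonal holds
    root-to-tip depths.  With ``normalize=True`` the matrix is divided by
    the maximum root-to-tip depth.
    """
    if tree.seed_node is None:
        raise ValueError("tree has no root")
    depth: dict = {tree.seed_node: 0.0}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        depth[nd] = depth[nd.parent_node] + (nd.edge.length or 0.0)
    leaves = [lf for lf in tree.leaf_node_iter()]
    labels = [lf.taxon.label for lf in leaves]
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))
    tipsets: dict = {}
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            i = index[nd.taxon.label]
            C[i, i] = depth[nd]
            tipsets[nd] = [i]
        else:
            groups = [tipsets.pop(ch) for ch in nd.child_nodes()]
            d = depth[nd]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        C[a, groups[gj]] = d
                        C[groups[gj], a] = d
            tipsets[nd] = [t for g in groups for t in g]
    pc = PhyloCovariance(C, labels)
    if taxa is not None:
        missing = set(taxa) - set(labels)
        if missing:
            raise ValueError(f"taxa not in tree: {sorted(missing)}")
        pc = pc.reorder(list(taxa))
    if normalize:
        scale = float(np.max(np.diag(pc.matrix)))
        if scale <= 0:
            raise ValueError("tree has zero depth")
        pc = PhyloCovariance(pc.matrix / scale, pc.taxa, depth_scale=scale)
    return pc


def lambda_transform(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's λ transform: off-diagonals scaled by λ, diagonal unchanged."""
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------

@dataclass
class LambdaFit:
    """Maximum-likelihood Pagel's λ with dual likelihood-ratio tests."""

    lam: float
    loglik: float
    loglik0: float   # at λ = 0
    loglik1: float   # at λ = 1
    mu: float
    sigma2: float
    p_lambda0: float  # H0: λ = 0
    p_lambda1: float  # H0: λ = 1
    flat_likelihood: bool = False


def _mvn_profile_loglik(y: np.ndarray, V: np.ndarray) -> tuple[float, float, float]:
    """Profile log-likelihood of y ~ MVN(μ1, σ²V) with μ, σ² at their MLEs.

    Returns (loglik, mu_hat, sigma2_hat).  σ̂² uses the ML (1/n) convention,
    matching the likelihood-ratio construction of the signal tests.
    """
    n = y.size
    cf = linalg.cho_factor(V, lower=True)
    ones = np.ones(n)
    Vinv_y = linalg.cho_solve(cf, y)
    Vinv_1 = linalg.cho_solve(cf, ones)
    mu = float(ones @ Vinv_y / (ones @ Vinv_1))
    r = y - mu
    sigma2 = float(r @ linalg.cho_solve(cf, r) / n)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    if sigma2 <= 0:
        return -np.inf, mu, 0.0
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return float(ll), mu, sigma2


def fit_lambda(y: np.ndarray, C: PhyloCovariance | np.ndarray,
               grid_points: int = 21, tol: float = 1e-6) -> LambdaFit:
    """ML estimate of Pagel's λ on [0, 1] with LR tests against 0 and 1.

    The mean and variance are profiled out in closed form (GLS mean, mean
    squared Mahalanobis residual); λ is found by a coarse grid followed by
    bounded 1-D maximization.  Both LR statistics are referred to χ²(1); the
    test against the λ=1 boundary keeps the plain χ²(1) reference, which is
    conservative there.
    """
    y = np.asarray(y, dtype=float)
    Cm = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 species to estimate lambda")
    if Cm.shape != (n, n):
        raise ValueError("covariance matrix does not match response length")

    def nll(lam: float) -> float:
        try:
            ll, _, _ = _mvn_profile_loglik(y, lambda_transform(Cm, lam))
        except np.linalg.LinAlgError:
            return np.inf
        return -ll

    grid = np.linspace(0.0, 1.0, grid_points)
    grid_nll = np.array([nll(g) for g in grid])
    if not np.all(np.isfinite(grid_nll)):
        raise np.linalg.LinAlgError("singular lambda-transformed covariance")
    flat = float(grid_nll.max() - grid_nll.min()) < 1e-8
    best = int(np.argmin(grid_nll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_points - 1)]
    if flat:
        lam_hat = float(grid[best])
    else:
        res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                       options={"xatol": tol})
        lam_hat = float(res.x)
        # never return a worse point than the grid found
        if nll(lam_hat) > grid_nll[best]:
            lam_hat = float(grid[best])
    ll_hat, mu, sigma2 = _mvn_profile_loglik(y, lambda_transform(Cm, lam_hat))
    ll0 = -float(grid_nll[0])
    ll1 = -float(grid_nll[-1])
    if ll_hat < max(ll0, ll1):  # boundary is the optimum
        if ll0 >= ll1 and ll0 > ll_hat:
            lam_hat, ll_hat = 0.0, ll0
        elif ll1 > ll_hat:
            lam_hat, ll_hat = 1.0, ll1
        ll_hat, mu, sigma2 = _mvn_profile_loglik(y, lambda_transform(Cm, lam_hat))
    lr0 = max(2.0 * (ll_hat - ll0), 0.0)
    lr1 = max(2.0 * (ll_hat - ll1), 0.0)
    return LambdaFit(
        lam=lam_hat, loglik=ll_hat, loglik0=ll0, loglik1=ll1,
        mu=mu, sigma2=sigma2,
        p_lambda0=float(stats.chi2.sf(lr0, df=1)),
        p_lambda1=float(stats.chi2.sf(lr1, df=1)),
        flat_likelihood=flat,
    )


# ---------------------------------------------------------------------------
# PGLS
# ---------------------------------------------------------------------------

@dataclass
class PGLSFit:
    """Generalized least squares fit under a phylogenetic correlation."""

    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    r_squared: float
    sigma2: float
    correlation: str
    lam: Optional[float]
    n: int
    df_resid: int
    names: list[str]


def pgls(y: np.ndarray, X: np.ndarray, C: PhyloCovariance | np.ndarray,
         correlation: str = "BM", lam: Optional[float] = None,
         names: Optional[Sequence[str]] = None) -> PGLSFit:
    """Phylogenetic generalized least squares.

    β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y with V = C_λ; standard errors from the GLS
    covariance with σ̂² = RSS/(n−p); R² computed in whitened space against
    the GLS intercept-only fit.  ``correlation``:

    * ``"BM"`` — λ = 1 (plain Brownian covariance);
    * ``"lambda-fixed"`` — λ supplied via ``lam``;
    * ``"lambda-estimated"`` — λ chosen by ML profile over [0, 1];
    * ``"identity"`` — V = I, reducing exactly to ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    Cm = C.matrix if isinstance(C, PhyloCovariance) else np.asarray(C, dtype=float)

    if correlation == "identity":
        V = np.eye(n)
        lam_used: Optional[float] = None
    elif correlation == "BM":
        V = Cm
        lam_used = 1.0
    elif correlation == "lambda-fixed":
        if lam is None:
            raise ValueError("lambda-fixed correlation requires lam")
        V = lambda_transform(Cm, lam)
        lam_used = lam
    elif correlation == "lambda-estimated":
        def nll(l: float) -> float:
            Vl = lambda_transform(Cm, l)
            cf = linalg.cho_factor(Vl, lower=True)
            W = linalg.cho_solve(cf, X)
            b = np.linalg.solve(X.T @ W, X.T @ linalg.cho_solve(cf, y))
            r = y - X @ b
            s2 = float(r @ linalg.cho_solve(cf, r)) / n
            logdet = 2 * np.sum(np.log(np.diag(cf[0])))
            return 0.5 * (n * np.log(2 * np.pi * s2) + logdet + n)
        res = optimize.minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": 1e-6})
        lam_used = float(res.x)
        V = lambda_transform(Cm, lam_used)
    else:
        raise ValueError(f"unknown correlation structure {correlation!r}")

    cf = linalg.cho_factor(V, lower=True)
    L = np.tril(cf[0])
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    rank = np.linalg.matrix_rank(Xw)
    if rank < p:
        _, _, piv = linalg.qr(Xw, pivoting=True)
        aliased = [names[j] for j in sorted(piv[rank:])]
        raise ValueError(f"design is rank deficient; aliased columns: {aliased}")
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    df_resid = n - p
    sigma2 = rss / df_resid
    cov = sigma2 * np.linalg.inv(XtX)
    bse = np.sqrt(np.diag(cov))
    tvals = beta / bse
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=df_resid)
    # TSS in whitened space around the GLS intercept-only mean
    ones_w = linalg.solve_triangular(L, np.ones(n), lower=True)
    mu_gls = float(ones_w @ yw / (ones_w @ ones_w))
    tss = float(np.sum((yw - mu_gls * ones_w) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return PGLSFit(params=beta, bse=bse, tvalues=tvals, pvalues=pvals,
                   r_squared=r2, sigma2=sigma2, correlation=correlation,
                   lam=lam_used, n=n, df_resid=df_resid, names=list(names))


# ---------------------------------------------------------------------------
# Collinearity screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenReport:
    """Every predictor dropped by the collinearity screen, with its statistic."""

    retained: list[str]
    dropped: list[dict]


def _indicator_frame(df: pd.DataFrame, predictors: Sequence[str]
                     ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Numeric columns per predictor: continuous as-is, categoricals as
    indicator columns with the first (sorted) level as reference."""
    cols: dict[str, np.ndarray] = {}
    groups: dict[str, list[str]] = {}
    for name in predictors:
        s = df[name]
        if pd.api.types.is_numeric_dtype(s):
            cols[name] = s.to_numpy(dtype=float)
            groups[name] = [name]
        else:
            levels = sorted(s.dropna().unique())
            groups[name] = []
            for lev in levels[1:]:
                col = f"{name}[{lev}]"
                cols[col] = (s == lev).to_numpy(dtype=float)
                groups[name].append(col)
            if not groups[name]:  # single-level categorical is constant
                col = f"{name}[{levels[0] if levels else '?'}]"
                cols[col] = np.ones(len(s))
                groups[name] = [col]
    return pd.DataFrame(cols, index=df.index), groups


def _gvif(R: np.ndarray, idx: np.ndarray) -> float:
    """Generalized VIF (determinant form) of the column block ``idx``
    within correlation matrix ``R``; equals plain VIF for a single column."""
    other = np.setdiff1d(np.arange(R.shape[0]), idx)
    det_all = np.linalg.det(R)
    det_1 = np.linalg.det(R[np.ix_(idx, idx)])
    det_2 = np.linalg.det(R[np.ix_(other, other)]) if other.size else 1.0
    if det_all <= 0:
        return np.inf
    return float(det_1 * det_2 / det_all)


def collinearity_screen(df: pd.DataFrame, predictors: Optional[Sequence[str]] = None,
                        r_max: float = 0.75, vif_max: float = 10.0) -> ScreenReport:
    """Two-pass predictor screen: pairwise correlation, then variance inflation.

    Pass 1 repeatedly inspects the worst pair of indicator/continuous columns
    from *different* predictors with |r| >= ``r_max`` and drops the whole
    predictor whose columns have the larger mean absolute correlation to all
    others.  Pass 2 drops the predictor with the highest generalized VIF
    (Fox–Monette determinant form, compared on the GVIF^(1/df) scale so a
    single-column predictor faces the plain VIF < ``vif_max`` rule) until all
    pass.  Constant predictors are dropped with a warning before screening.
    """
    if predictors is None:
        predictors = [c for c in df.columns if c != "species"]
    predictors = list(predictors)
    dropped: list[dict] = []

    # constant predictors are uninformative and break correlations
    for name in list(predictors):
        s = df[name].dropna()
        if s.nunique() <= 1:
            warnings.warn(f"constant predictor {name!r} dropped before screening",
                          stacklevel=2)
            dropped.append({"predictor": name, "pass": "constant", "statistic": np.nan})
            predictors.remove(name)

    def stats_frame(preds: list[str]):
        num, groups = _indicator_frame(df, preds)
        return num, groups

    # pass 1: pairwise correlation among indicator columns of different predictors
    while len(predictors) >= 2:
        num, groups = stats_frame(predictors)
        corr = num.corr().to_numpy()
        np.fill_diagonal(corr, 0.0)
        col_names = list(num.columns)
        owner = {c: p for p, cs in groups.items() for c in cs}
        worst: Optional[tuple[float, str, str]] = None
        for i in range(len(col_names)):
            for j in range(i + 1, len(col_names)):
                if owner[col_names[i]] == owner[col_names[j]]:
                    continue
                r = abs(corr[i, j])
                if r >= r_max and (worst is None or r > worst[0]):
                    worst = (r, col_names[i], col_names[j])
        if worst is None:
            break
        r, ci, cj = worst
        mean_abs = np.nanmean(np.abs(corr), axis=0)
        score = {p: np.mean([mean_abs[col_names.index(c)] for c in groups[p]])
                 for p in (owner[ci], owner[cj])}
        victim = max(score, key=lambda p: score[p])
        dropped.append({"predictor": victim, "pass": "pairwise-r", "statistic": r})
        predictors.remove(victim)

    # pass 2: generalized VIF per whole predictor
    while len(predictors) >= 2:
        num, groups = stats_frame(predictors)
        R = num.corr().to_numpy()
        gvif_scaled = {}
        for p in predictors:
            idx = np.array([list(num.columns).index(c) for c in groups[p]])
            g = _gvif(R, idx)
            gvif_scaled[p] = g ** (1.0 / len(idx)) if np.isfinite(g) else np.inf
        worst_p = max(gvif_scaled, key=lambda p: gvif_scaled[p])
        if gvif_scaled[worst_p] < vif_max:
            break
        dropped.append({"predictor": worst_p, "pass": "vif",
                        "statistic": gvif_scaled[worst_p]})
        predictors.remove(worst_p)

    return ScreenReport(retained=predictors, dropped=dropped)
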
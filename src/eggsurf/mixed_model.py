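"""Gaussian phylogenetic mixed model ("animal model") fitted by Gibbs sampling.

The model, on individual-level responses (one row per scan/specimen):

    y = Xβ + Z a + Z b + e
    a ~ N(0, σ²_p A)     phylogenetic effect, A = phylogenetic correlation
    b ~ N(0, σ²_s I)     species-identity effect
    e ~ N(0, σ²_e I)     residual

with weakly-informative inverse-gamma priors on the three variances and a
diffuse normal prior on β.  All full conditionals are conjugate, so the
sampler is a plain Gibbs scheme: β | rest and a | rest are multivariate
normal (the latter via the Cholesky of its precision, which involves A⁻¹),
b | rest is independent normal per species, and each variance | rest is
inverse gamma.  Draws are deterministic under the seed.

Posterior summaries follow MCMC practice: pMCMC = 2·min(P(>0), P(<0))
floored at 1/n_draws, and highest-posterior-density intervals as the
shortest contiguous window of sorted draws.  Posterior prediction over a
factorial grid of predictors multiplies the grid design matrix with the
fixed-effect draws in batches (random effects marginalized at zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg

from .phylo import PhyloCovariance, vcv

__all__ = [
    "ModelSpec",
    "FixedDesign",
    "PosteriorSamples",
    "PredictionGrid",
    "fit_mcmc",
    "pmcmc",
    "hpd",
    "build_grid",
    "posterior_predict",
    "effective_sample_size",
]


@dataclass
class ModelSpec:
    """Model formula and MCMC controls.

    The random structure is fixed (phylogenetic + species identity); only
    the response and fixed effects vary.  Default controls are deliberately
    small-scale; the variance priors are inverse-gamma(shape, scale) and the
    fixed effects get a diffuse N(0, ``fixed_prior_variance``) prior.
    """

    response: str
    fixed: list = field(default_factory=list)
    iterations: int = 20000
    burn_in: int = 5000
    thinning: int = 10
    prior_shape: float = 0.001
    prior_scale: float = 0.001
    fixed_prior_variance: float = 1e8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.iterations > self.burn_in >= 0):
            raise ValueError("need iterations > burn_in >= 0")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if (self.iterations - self.burn_in) // self.thinning < 100:
            raise ValueError("controls retain fewer than 100 draws")
        if min(self.prior_shape, self.prior_scale, self.fixed_prior_variance) <= 0:
            raise ValueError("prior parameters must be positive")

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


class FixedDesign:
    """Design-matrix builder shared between fitting and prediction.

    Continuous predictors enter as-is; categoricals as indicator columns
    with the first (sorted) level as reference.  The encoding is frozen at
    fit time so prediction grids are coded identically.
    """

    def __init__(self, df: pd.DataFrame, predictors: Sequence[str]):
        self.predictors = list(predictors)
        self.kinds: dict[str, str] = {}
        self.levels: dict[str, list[str]] = {}
        for name in self.predictors:
            if name not in df.columns:
                raise ValueError(f"predictor column missing from data: {name!r}")
            if pd.api.types.is_numeric_dtype(df[name]):
                self.kinds[name] = "continuous"
            else:
                self.kinds[name] = "categorical"
                self.levels[name] = sorted(df[name].dropna().unique())
        self.names = ["(Intercept)"]
        for name in self.predictors:
            if self.kinds[name] == "continuous":
                self.names.append(name)
            else:
                self.names += [f"{name}[{lev}]" for lev in self.levels[name][1:]]

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        missing = [p for p in self.predictors if p not in df.columns]
        if missing:
            raise ValueError(f"columns missing from data: {missing}")
        cols = [np.ones(len(df))]
        for name in self.predictors:
            if self.kinds[name] == "continuous":
                cols.append(df[name].to_numpy(dtype=float))
            else:
                seen = set(df[name].dropna().unique())
                unknown = seen - set(self.levels[name])
                if unknown:
                    raise ValueError(f"unseen level(s) {sorted(unknown)} "
                                     f"for predictor {name!r}")
                for lev in self.levels[name][1:]:
                    cols.append((df[name] == lev).to_numpy(dtype=float))
        return np.column_stack(cols)


@dataclass
class PosteriorSamples:
    """Retained draws of fixed effects and variance components."""

    beta: np.ndarray          # (n_draws, p)
    beta_names: list[str]
    var_phylo: np.ndarray     # (n_draws,)
    var_species: np.ndarray
    var_resid: np.ndarray
    ess: dict
    seed: int
    design: Optional[FixedDesign] = None
    species: Optional[list[str]] = None

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def effect(self, name: str) -> np.ndarray:
        variances = {"var_phylo": self.var_phylo,
                     "var_species": self.var_species,
                     "var_resid": self.var_resid}
        if name in variances:
            return variances[name]
        if name not in self.beta_names:
            raise KeyError(f"no effect named {name!r}; have {self.beta_names}")
        return self.beta[:, self.beta_names.index(name)]


@dataclass
class PredictionGrid:
    """Posterior predictions over a factorial predictor grid."""

    table: pd.DataFrame  # grid columns + mean + hpdXX_low/high


# ---------------------------------------------------------------------------
# Gibbs full conditionals (unit-tested against closed forms)
# ---------------------------------------------------------------------------

def _sample_mvn_precision(rng: np.random.Generator, precision: np.ndarray,
                          linear: np.ndarray) -> np.ndarray:
    """Draw from N(P⁻¹h, P⁻¹) given precision P and linear term h."""
    L = linalg.cholesky(precision, lower=True)
    mean = linalg.cho_solve((L, True), linear)
    z = rng.standard_normal(linear.size)
    return mean + linalg.solve_triangular(L.T, z, lower=False)


def _draw_beta(rng, X, target, sigma2_e, prior_var):
    """β | rest ~ N with precision X'X/σ²_e + I/v0, linear X'target/σ²_e."""
    p = X.shape[1]
    prec = X.T @ X / sigma2_e + np.eye(p) / prior_var
    return _sample_mvn_precision(rng, prec, X.T @ target / sigma2_e)

def _draw_phylo_effects(rng, counts, Ainv, per_species_sum, sigma2_p, sigma2_e):
    """a | rest ~ N with precision diag(counts)/σ²_e + A⁻¹/σ²_p."""
    prec = Ainv / sigma2_p + np.diag(counts / sigma2_e)
    return _sample_mvn_precision(rng, prec, per_species_sum / sigma2_e)

def _draw_species_effects(rng, counts, per_species_sum, sigma2_s, sigma2_e):
    """b | rest — independent normals per species."""
    prec = counts / sigma2_e + 1.0 / sigma2_s
    mean = (per_species_sum / sigma2_e) / prec
    return mean + rng.standard_normal(counts.size) / np.sqrt(prec)

def _draw_variance(rng, shape0, scale0, quad, k):
    """σ² | rest ~ InvGamma(shape0 + k/2, scale0 + quad/2)."""
    shape = shape0 + 0.5 * k
    scale = scale0 + 0.5 * quad
    return scale / rng.gamma(shape)


def fit_mcmc(data: pd.DataFrame, tree: dendropy.Tree | PhyloCovariance,
             spec: ModelSpec, species: str = "species") -> PosteriorSamples:
    """Fit the phylogenetic mixed model by Gibbs sampling.

    ``data`` holds one row per individual measurement with the response
    column ``spec.response``, a ``species`` column matching tree tips, and
    the fixed-effect predictor columns (constant within species).  The
    phylogenetic correlation uses the plain Brownian covariance (λ = 1)
    converted to a correlation matrix; signal flexibility is carried by the
    σ²_p / σ²_s split.
    """
    sp_labels = sorted(data[species].unique())
    if len(sp_labels) < 2:
        raise ValueError("need at least 2 species")
    pc = tree if isinstance(tree, PhyloCovariance) else vcv(tree, normalize=True)
    missing = sorted(set(sp_labels) - set(pc.taxa))
    if missing:
        raise ValueError(f"species not on the tree: {missing}")
    pc = pc.reorder(sp_labels)
    A = pc.correlation()
    try:
        A_chol = linalg.cholesky(A + 1e-10 * np.eye(len(sp_labels)), lower=True)
    except linalg.LinAlgError as err:
        raise ValueError("phylogenetic correlation is not positive definite") from err
    Ainv = linalg.cho_solve((A_chol, True), np.eye(len(sp_labels)))
    Ainv = 0.5 * (Ainv + Ainv.T)

    design = FixedDesign(data, spec.fixed)
    X = design.matrix(data)
    y = data[spec.response].to_numpy(dtype=float)
    sp_idx = pd.Categorical(data[species], categories=sp_labels).codes
    S = len(sp_labels)
    counts = np.bincount(sp_idx, minlength=S).astype(float)
    n, p = X.shape

    rng = np.random.default_rng(spec.seed)
    # initialization: OLS for beta, residual variance split three ways
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid0 = y - X @ beta
    v0 = max(float(resid0.var()), 1e-6)
    sigma2_p = sigma2_s = sigma2_e = v0 / 3.0
    a = np.zeros(S)
    b = np.zeros(S)

    n_ret = spec.n_retained
    beta_draws = np.empty((n_ret, p))
    vp_draws = np.empty(n_ret)
    vs_draws = np.empty(n_ret)
    ve_draws = np.empty(n_ret)
    keep = 0
    for it in range(spec.iterations):
        u = a[sp_idx] + b[sp_idx]
        beta = _draw_beta(rng, X, y - u, sigma2_e, spec.fixed_prior_variance)
        fixed_part = X @ beta
        r = y - fixed_part - b[sp_idx]
        a = _draw_phylo_effects(rng, counts, Ainv,
                                np.bincount(sp_idx, weights=r, minlength=S),
                                sigma2_p, sigma2_e)
        r = y - fixed_part - a[sp_idx]
        b = _draw_species_effects(rng, counts,
                                  np.bincount(sp_idx, weights=r, minlength=S),
                                  sigma2_s, sigma2_e)
        e = y - fixed_part - a[sp_idx] - b[sp_idx]
        sigma2_p = _draw_variance(rng, spec.prior_shape, spec.prior_scale,
                                  float(a @ (Ainv @ a)), S)
        sigma2_s = _draw_variance(rng, spec.prior_shape, spec.prior_scale,
                                  float(b @ b), S)
        sigma2_e = _draw_variance(rng, spec.prior_shape, spec.prior_scale,
                                  float(e @ e), n)
        if it >= spec.burn_in and (it - spec.burn_in) % spec.thinning == 0 \
                and keep < n_ret:
            beta_draws[keep] = beta
            vp_draws[keep] = sigma2_p
            vs_draws[keep] = sigma2_s
            ve_draws[keep] = sigma2_e
            keep += 1
    ess = {name: effective_sample_size(beta_draws[:, j])
           for j, name in enumerate(design.names)}
    ess["var_phylo"] = effective_sample_size(vp_draws)
    ess["var_species"] = effective_sample_size(vs_draws)
    ess["var_resid"] = effective_sample_size(ve_draws)
    return PosteriorSamples(beta=beta_draws[:keep], beta_names=design.names,
                            var_phylo=vp_draws[:keep], var_species=vs_draws[:keep],
                            var_resid=ve_draws[:keep], ess=ess, seed=spec.seed,
                            design=design, species=sp_labels)


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def pmcmc(samples: PosteriorSamples | np.ndarray, effect: Optional[str] = None
          ) -> float:
    """MCMC two-sided significance: 2·min(P(draw > 0), P(draw < 0)),
    floored at 1/n_draws."""
    draws = samples.effect(effect) if isinstance(samples, PosteriorSamples) \
        else np.asarray(samples, dtype=float)
    n = draws.size
    if n == 0:
        raise ValueError("no draws")
    p = 2.0 * min(np.mean(draws > 0), np.mean(draws < 0))
    return float(max(p, 1.0 / n))


def hpd(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval of sorted draws containing ⌈mass·n⌉ draws."""
    draws = np.sort(np.asarray(draws, dtype=float))
    n = draws.size
    if n < 2:
        if n == 1:
            return float(draws[0]), float(draws[0])
        raise ValueError("need at least 2 draws")
    if not (0 < mass < 1):
        raise ValueError("mass must lie in (0, 1)")
    m = int(math.ceil(mass * n))
    m = min(max(m, 1), n)
    widths = draws[m - 1:] - draws[: n - m + 1]
    i = int(np.argmin(widths))
    return float(draws[i]), float(draws[i + m - 1])


def effective_sample_size(x: np.ndarray) -> float:
    """ESS via Geyer's initial-positive-sequence autocorrelation sum."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4 or x.std() == 0:
        return float(n)
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[n - 1:] / n
    rho = acov / acov[0]
    # sum consecutive pairs while positive
    s = 0.0
    for k in range(1, n - 1, 2):
        pair = rho[k] + rho[k + 1] if k + 1 < n else rho[k]
        if pair <= 0:
            break
        s += pair
    return float(min(n, n / (1.0 + 2.0 * s)))


# ---------------------------------------------------------------------------
# Posterior prediction grid
# ---------------------------------------------------------------------------

def build_grid(df: pd.DataFrame, predictors: Sequence[str], bins: int = 3
               ) -> pd.DataFrame:
    """Factorial grid over predictors, lexicographic in sorted predictor name.

    Continuous predictors contribute ``bins`` equally spaced representative
    values from min to max (3 bins -> {min, midpoint, max}); categoricals
    contribute every observed level.  A constant continuous predictor yields
    a single value with a warning.
    """
    import itertools
    import warnings

    axes: list[tuple[str, list]] = []
    for name in sorted(predictors):
        s = df[name].dropna()
        if pd.api.types.is_numeric_dtype(s):
            lo, hi = float(s.min()), float(s.max())
            if lo == hi:
                warnings.warn(f"constant continuous predictor {name!r}; "
                              "grid uses its single value", stacklevel=2)
                vals: list = [lo]
            else:
                vals = list(np.linspace(lo, hi, bins))
        else:
            vals = sorted(s.unique())
        axes.append((name, vals))
    rows = list(itertools.product(*(vals for _, vals in axes)))
    return pd.DataFrame(rows, columns=[name for name, _ in axes])


def posterior_predict(grid: pd.DataFrame, samples: PosteriorSamples,
                      batch_size: int = 500) -> PredictionGrid:
    """Posterior of the fixed-effect linear predictor Xβ on each grid row.

    Random effects are marginalized at zero.  Rows are processed in batches
    of ``batch_size`` (memory control only — results are identical for any
    batch size).  Each row gets the posterior mean and 50/80/95% HPD bounds.
    """
    if samples.design is None:
        raise ValueError("samples carry no design; fit with fit_mcmc first")
    if batch_size < 1:
        raise ValueError("batch size must be >= 1")
    n = len(grid)
    means = np.empty(n)
    bounds = {m: (np.empty(n), np.empty(n)) for m in (0.50, 0.80, 0.95)}
    for start in range(0, n, batch_size):
        batch = grid.iloc[start:start + batch_size]
        Xb = samples.design.matrix(batch)
        draws = Xb @ samples.beta.T  # (rows, n_draws)
        means[start:start + len(batch)] = draws.mean(axis=1)
        for m, (lo, hi) in bounds.items():
            for i in range(len(batch)):
                lo[start + i], hi[start + i] = hpd(draws[i], m)
    out = grid.copy()
    out["mean"] = means
    for m, (lo, hi) in bounds.items():
        tag = f"hpd{int(m * 100)}"
        out[f"{tag}_low"] = lo
        out[f"{tag}_high"] = hi
    return PredictionGrid(table=out)
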
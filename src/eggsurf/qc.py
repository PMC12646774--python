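"""Quality control and aggregation of scan-level texture values.

Covers the four steps between raw per-scan texture parameters and the
species-level table the comparative models consume:

1. repeatability of repeated scans on the same fragment (one-way
   random-effects intraclass correlation, with a parametric-bootstrap CI);
2. two-stage aggregation — scans are averaged per specimen, then specimen
   means are averaged per species (never a pooled single-stage mean);
3. Cook's-distance influence filtering of specimen values with the species
   retention rules: a single-egg species loses its egg if flagged; a
   multi-egg species with *all* eggs flagged keeps them all; otherwise only
   the flagged eggs are dropped;
4. response transforms (log10 Sa, Ssk untouched, log10 Sku) and the join
   against the life-history trait table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import ALL_PREDICTORS, TraitRecord, trait_records_to_frame

logger = logging.getLogger("eggsurf")

__all__ = [
    "RepeatabilityResult",
    "CooksFilterReport",
    "repeatability",
    "aggregate",
    "cooks_filter",
    "build_study_table",
]


# ---------------------------------------------------------------------------
# Repeatability (one-way random-effects ICC)
# ---------------------------------------------------------------------------

@dataclass
class RepeatabilityResult:
    """Repeatability R = σ²_between / (σ²_between + σ²_within)."""

    r: float
    var_between: float
    var_within: float
    ci_low: float
    ci_high: float
    n_specimens: int
    n_scans: int
    degenerate: bool = False


def _anova_components(values: np.ndarray, groups: np.ndarray
                      ) -> tuple[float, float]:
    """One-way ANOVA moment estimates of (σ²_between, σ²_within).

    Handles unbalanced designs via the standard n0 correction; negative
    between-group estimates are truncated at zero.
    """
    labs, counts = np.unique(groups, return_counts=True)
    a = labs.size
    N = values.size
    grand = values.mean()
    group_means = np.array([values[groups == g].mean() for g in labs])
    ss_between = float(np.sum(counts * (group_means - grand) ** 2))
    ss_within = float(np.sum((values - group_means[np.searchsorted(labs, groups)]) ** 2))
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a) if N > a else 0.0
    n0 = (N - np.sum(counts ** 2) / N) / (a - 1)
    var_b = max((ms_between - ms_within) / n0, 0.0)
    return var_b, ms_within


def repeatability(df: pd.DataFrame, value: str = "value",
                  group: str = "specimen", n_boot: int = 1000,
                  seed: int = 0, ci_level: float = 0.95) -> RepeatabilityResult:
    """Repeatability of repeated scans grouped by specimen.

    Uses the ANOVA moment estimator for balanced designs and REML (via a
    random-intercept mixed model) for unbalanced ones; the confidence
    interval is a parametric bootstrap (``n_boot`` replicates, ANOVA
    estimator inside the loop).  Specimens with a single scan are dropped
    with a logged warning.
    """
    counts = df.groupby(group)[value].count()
    singles = counts[counts < 2].index
    if len(singles):
        logger.warning("dropping %d specimen(s) with a single scan from the "
                       "repeatability test", len(singles))
        df = df[~df[group].isin(singles)]
    counts = df.groupby(group)[value].count()
    if len(counts) < 2:
        raise ValueError("need at least 2 specimens with >= 2 scans")
    values = df[value].to_numpy(dtype=float)
    groups = df[group].to_numpy()

    if np.ptp(values) == 0.0:  # all values identical everywhere
        return RepeatabilityResult(r=1.0, var_between=0.0, var_within=0.0,
                                   ci_low=1.0, ci_high=1.0,
                                   n_specimens=len(counts), n_scans=len(values),
                                   degenerate=True)

    balanced = counts.nunique() == 1
    if balanced:
        var_b, var_w = _anova_components(values, groups)
    else:
        codes = pd.factorize(groups)[0]
        model = sm.MixedLM(values, np.ones((values.size, 1)), groups=codes)
        fit = model.fit(reml=True)
        var_w = float(fit.scale)
        var_b = float(np.asarray(fit.cov_re)[0, 0])
    total = var_b + var_w
    r = 1.0 if total == 0.0 else var_b / total

    # parametric bootstrap CI under the fitted components, same design
    rng = np.random.default_rng(seed)
    sizes = counts.to_numpy()
    boot = np.empty(n_boot)
    sd_b, sd_w = np.sqrt(var_b), np.sqrt(var_w)
    labels = np.repeat(np.arange(sizes.size), sizes)
    for b in range(n_boot):
        mu = rng.normal(0.0, sd_b, sizes.size)
        sim = mu[labels] + rng.normal(0.0, sd_w, labels.size)
        vb, vw = _anova_components(sim, labels)
        boot[b] = 1.0 if vb + vw == 0 else vb / (vb + vw)
    alpha = 1 - ci_level
    lo, hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2])
    return RepeatabilityResult(r=float(r), var_between=float(var_b),
                               var_within=float(var_w),
                               ci_low=float(lo), ci_high=float(hi),
                               n_specimens=len(counts), n_scans=len(values))


# ---------------------------------------------------------------------------
# Two-stage aggregation
# ---------------------------------------------------------------------------

def aggregate(df: pd.DataFrame, value_cols: Sequence[str],
              species: str = "species", specimen: str = "specimen"
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan values -> specimen means -> species means (two-stage).

    The two-stage mean weights every specimen equally within its species no
    matter how many scans survived QC, which a pooled single-stage mean would
    not.  Returns ``(specimen_means, species_means)`` with scan/specimen
    counts carried through.
    """
    value_cols = list(value_cols)
    spec_means = (df.groupby([species, specimen], sort=True)[value_cols]
                  .mean().reset_index())
    spec_counts = (df.groupby([species, specimen], sort=True)
                   .size().rename("n_scans").reset_index())
    spec_means = spec_means.merge(spec_counts, on=[species, specimen])
    sp_means = (spec_means.groupby(species, sort=True)[value_cols]
                .mean().reset_index())
    sp_counts = (spec_means.groupby(species, sort=True)
                 .size().rename("n_specimens").reset_index())
    sp_means = sp_means.merge(sp_counts, on=species)
    return spec_means, sp_means


# ---------------------------------------------------------------------------
# Cook's-distance influence filtering
# ---------------------------------------------------------------------------

@dataclass
class CooksFilterReport:
    """Per-specimen Cook's distances, flags and the species rule applied."""

    table: pd.DataFrame  # specimen, species, value, cooks_d, flagged, kept, rule
    cutoff: float


def cooks_distance(values: np.ndarray) -> np.ndarray:
    """Cook's D of each observation under the intercept-only linear model."""
    values = np.asarray(values, dtype=float)
    model = sm.OLS(values, np.ones((values.size, 1))).fit()
    return model.get_influence().cooks_distance[0]


def cooks_filter(df: pd.DataFrame, value: str = "value",
                 species: str = "species", specimen: str = "specimen",
                 cutoff: Optional[float] = None
                 ) -> tuple[CooksFilterReport, pd.DataFrame]:
    """Flag influential specimen values and apply the species retention rules.

    Cook's distance is computed from the intercept-only model over *all*
    specimens for the response (default cutoff 4/n).  Rules per species:
    ``single-egg-drop`` (one specimen, flagged -> excluded),
    ``all-influential-retain`` (multi-egg, all flagged -> all retained),
    ``partial-drop`` (only flagged ones excluded), ``none``.
    """
    n = len(df)
    if n < 3:
        raise ValueError("need at least 3 specimens for influence filtering")
    if cutoff is None:
        cutoff = 4.0 / n
    d = cooks_distance(df[value].to_numpy())
    out = df[[species, specimen, value]].copy()
    out["cooks_d"] = d
    out["flagged"] = d > cutoff
    out["kept"] = True
    out["rule"] = "none"
    for sp, idx in out.groupby(species).groups.items():
        flags = out.loc[idx, "flagged"]
        if not flags.any():
            continue
        if len(idx) == 1:
            out.loc[idx, "kept"] = False
            out.loc[idx, "rule"] = "single-egg-drop"
        elif flags.all():
            out.loc[idx, "rule"] = "all-influential-retain"
        else:
            out.loc[idx, "rule"] = "partial-drop"
            out.loc[idx[flags.to_numpy()], "kept"] = False
    report = CooksFilterReport(table=out, cutoff=float(cutoff))
    filtered = df.loc[out.index[out["kept"]]].copy()
    return report, filtered


# ---------------------------------------------------------------------------
# Study table
# ---------------------------------------------------------------------------

def build_study_table(species_means: pd.DataFrame,
                      traits: Sequence[TraitRecord] | pd.DataFrame,
                      species: str = "species") -> pd.DataFrame:
    """Join species texture means to life-history traits, transforming the
    responses (log10 Sa, Ssk untouched, log10 Sku).

    Species present on only one side of the join are dropped and logged;
    non-positive Sa/Sku and duplicated species raise.
    """
    df = species_means.copy()
    if df[species].duplicated().any():
        dups = sorted(df.loc[df[species].duplicated(), species])
        raise ValueError(f"duplicated species in texture table: {dups}")
    for col, new in (("sa", "log10_sa"), ("sku", "log10_sku")):
        if (df[col] <= 0).any():
            bad = sorted(df.loc[df[col] <= 0, species])
            raise ValueError(f"non-positive {col} for species {bad}; "
                             "cannot log10-transform")
        df[new] = np.log10(df[col])
    trait_df = traits if isinstance(traits, pd.DataFrame) \
        else trait_records_to_frame(list(traits))
    if trait_df[species].duplicated().any():
        dups = sorted(trait_df.loc[trait_df[species].duplicated(), species])
        raise ValueError(f"duplicated species in trait table: {dups}")
    merged = df.merge(trait_df, on=species, how="inner")
    lost_tex = sorted(set(df[species]) - set(merged[species]))
    lost_tr = sorted(set(trait_df[species]) - set(merged[species]))
    if lost_tex:
        logger.info("species with texture but no traits dropped: %s", lost_tex)
    if lost_tr:
        logger.info("species with traits but no texture dropped: %s", lost_tr)
    keep = [species, "log10_sa", "ssk", "log10_sku"]
    if "n_specimens" in merged.columns:
        keep.append("n_specimens")
    keep += [p for p in ALL_PREDICTORS if p in merged.columns]
    return merged[keep]
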
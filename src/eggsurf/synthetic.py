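"""Synthetic data with the statistical structure the analysis assumes.

Three generators:

* height maps — a spherical-cap base form plus a spatially correlated
  Gaussian field, optionally punched with pore-like pits (driving skewness
  negative, as on real porous eggshell) or studded with peaks, and with
  missing pixels concentrated at the scan edges/corners the way an
  interferometer loses data on a curved shell;
* Yule phylogenies with reproducible branch lengths;
* species trait tables and individual-level responses generated under a
  λ-transformed Brownian-motion phylogenetic effect plus a species-identity
  effect, fixed life-history effects, and within-specimen scan noise.

Every generator is bit-reproducible under its seed.  One shared integer seed
expands to per-component substreams by fixed offsets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import ndimage

from .io import (ALL_PREDICTORS, CATEGORICAL_LEVELS, CONTINUOUS_PREDICTORS,
                 HeightMap, TraitRecord)
from .phylo import lambda_transform, vcv

__all__ = [
    "SurfaceSpec",
    "TraitSimSpec",
    "gen_height_map",
    "gen_tree",
    "simulate_study",
    "SEED_SURFACE",
    "SEED_TREE",
    "SEED_TRAITS",
]

# fixed offsets expanding one shared seed into per-component substreams
SEED_SURFACE = 101
SEED_TREE = 211
SEED_TRAITS = 307


@dataclass
class SurfaceSpec:
    """Recipe for one synthetic scan.

    Defaults emulate the study's scan geometry: 768 × 576 px at ~0.83 µm
    pitch (636.61 × 477.25 µm² field of view).  ``base_radius_um`` is the
    spherical-cap radius (``inf`` = flat); pore/peak densities are per
    1000 px².
    """

    nrow: int = 576
    ncol: int = 768
    pitch: float = 0.829
    base_radius_um: float = math.inf
    field_sd: float = 50.0          # nm
    correlation_length: float = 3.0  # pixels
    pore_density: float = 0.0       # pores per 1000 px²
    pore_depth_mean: float = 200.0  # nm
    pore_depth_sd: float = 50.0     # nm
    pore_radius: float = 4.0        # pixels
    peak_density: float = 0.0
    peak_height_mean: float = 200.0
    peak_height_sd: float = 50.0
    peak_radius: float = 4.0
    edge_dropout: float = 0.0       # fraction of pixels invalidated
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_sd < 0 or self.pore_density < 0 or self.peak_density < 0:
            raise ValueError("densities and field sd must be non-negative")
        if not (0 <= self.edge_dropout < 1):
            raise ValueError("edge dropout fraction must lie in [0, 1)")


@dataclass
class TraitSimSpec:
    """Recipe for a simulated comparative study.

    The response is on the log10 Sa scale.  Species means follow
    Xβ + u_phylo + u_species with u_phylo ~ MVN(0, σ_p² C_λ) (C's diagonal
    normalized so the deepest tip is 1) and u_species ~ N(0, σ_s²);
    individual scans add N(0, σ_e²).  Sampling depths mirror the study's
    design: 1–10 specimens per species, three scans per specimen.
    """

    n_species: int = 100
    specimens_per_species: tuple[int, int] = (1, 10)
    scans_per_specimen: int = 3
    lam: float = 0.6
    sigma_phylo: float = 0.3
    sigma_species: float = 0.2
    sigma_resid: float = 0.1
    intercept: float = 3.0  # log10 Sa around 1000 nm
    fixed_effects: dict = field(default_factory=lambda: {
        ("maculation", "maculate"): 0.5,
        ("nest_type", "semi-enclosed"): -0.3,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.lam <= 1):
            raise ValueError("lambda must lie in [0, 1]")
        if min(self.sigma_phylo, self.sigma_species, self.sigma_resid) < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.scans_per_specimen < 1:
            raise ValueError("need at least one scan per specimen")


# ---------------------------------------------------------------------------
# Height maps
# ---------------------------------------------------------------------------

def _radial_cosine_bump(radius_px: float) -> np.ndarray:
    """Smooth unit-depth pit/peak profile: (1 + cos(pi r / R)) / 2 for r < R.

    Smooth (C¹) bumps survive second-order form correction essentially
    intact, emulating pore openings in the shell surface.
    """
    r_int = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r_int:r_int + 1, -r_int:r_int + 1]
    r = np.hypot(yy, xx)
    bump = np.where(r < radius_px, 0.5 * (1 + np.cos(np.pi * r / radius_px)), 0.0)
    return bump


def _stamp(canvas: np.ndarray, bump: np.ndarray, row: int, col: int,
           amplitude: float) -> None:
    half = bump.shape[0] // 2
    r0, r1 = row - half, row + half + 1
    c0, c1 = col - half, col + half + 1
    br0, bc0 = max(0, -r0), max(0, -c0)
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, canvas.shape[0]), min(c1, canvas.shape[1])
    canvas[r0:r1, c0:c1] += amplitude * bump[br0:br0 + (r1 - r0), bc0:bc0 + (c1 - c0)]


def gen_height_map(spec: SurfaceSpec) -> HeightMap:
    """Generate one synthetic scan according to ``spec`` (bit-reproducible)."""
    rng = np.random.default_rng(spec.seed)
    nrow, ncol = spec.nrow, spec.ncol
    heights = np.zeros((nrow, ncol))

    # spherical-cap base form (heights in nm, radius in µm)
    if math.isfinite(spec.base_radius_um):
        y_um = (np.arange(nrow) - (nrow - 1) / 2.0) * spec.pitch
        x_um = (np.arange(ncol) - (ncol - 1) / 2.0) * spec.pitch
        rr = y_um[:, None] ** 2 + x_um[None, :] ** 2
        R = spec.base_radius_um
        cap_um = R - np.sqrt(np.maximum(R * R - rr, 0.0))
        heights += cap_um * 1000.0  # µm -> nm

    # correlated Gaussian field: seeded white noise smoothed by a Gaussian
    # kernel truncated at 4 correlation lengths, rescaled to field sd
    if spec.field_sd > 0:
        white = rng.standard_normal((nrow, ncol))
        if spec.correlation_length > 0:
            fld = ndimage.gaussian_filter(white, spec.correlation_length,
                                          mode="reflect", truncate=4.0)
        else:
            fld = white
        sd = fld.std()
        if sd > 0:
            heights += fld * (spec.field_sd / sd)

    # pore-like pits (subtract) and peaks (add)
    for density, depth_mu, depth_sd, radius, sign in (
            (spec.pore_density, spec.pore_depth_mean, spec.pore_depth_sd,
             spec.pore_radius, -1.0),
            (spec.peak_density, spec.peak_height_mean, spec.peak_height_sd,
             spec.peak_radius, +1.0)):
        if density <= 0:
            continue
        n_features = rng.poisson(density * nrow * ncol / 1000.0)
        bump = _radial_cosine_bump(radius)
        rows = rng.integers(0, nrow, n_features)
        cols = rng.integers(0, ncol, n_features)
        amps = np.abs(rng.normal(depth_mu, depth_sd, n_features))
        for r, c, a in zip(rows, cols, amps):
            _stamp(heights, bump, int(r), int(c), sign * a)

    # missing pixels, preferentially at edges/corners: score each pixel by
    # its distance to the nearest edge plus seeded jitter, drop the lowest
    valid = np.ones((nrow, ncol), dtype=bool)
    if spec.edge_dropout > 0:
        ii = np.minimum(np.arange(nrow), np.arange(nrow)[::-1])
        jj = np.minimum(np.arange(ncol), np.arange(ncol)[::-1])
        d_edge = np.minimum(ii[:, None], jj[None, :]).astype(float)
        jitter = rng.exponential(scale=0.15 * max(nrow, ncol), size=(nrow, ncol))
        score = d_edge + jitter
        k = int(round(spec.edge_dropout * nrow * ncol))
        if k > 0:
            cut = np.partition(score.ravel(), k - 1)[k - 1]
            valid = score > cut
    heights = heights.copy()
    heights[~valid] = np.nan
    return HeightMap(heights, valid, spec.pitch, spec.pitch,
                     {"seed": spec.seed})


# ---------------------------------------------------------------------------
# Phylogenies
# ---------------------------------------------------------------------------

def gen_tree(n_tips: int, model: str = "yule", seed: int = 0,
             birth_rate: float = 1.0) -> dendropy.Tree:
    """Simulate a rooted Yule (pure-birth) tree with ``n_tips`` extant tips.

    Waiting times between speciations are Exponential(k·birth_rate) with k
    the number of extant lineages; a final waiting time gives the pendant
    edges positive length.  Tips are labelled T1..Tn in birth order.
    """
    if model != "yule":
        raise ValueError(f"unknown tree model {model!r}")
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    active = [tree.seed_node]
    while len(active) < n_tips:
        k = len(active)
        wait = rng.exponential(1.0 / (birth_rate * k))
        for nd in active:
            if nd is not tree.seed_node:
                nd.edge.length += wait
        idx = int(rng.integers(0, k))
        parent = active.pop(idx)
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            parent.add_child(child)
            active.append(child)
    final = rng.exponential(1.0 / (birth_rate * n_tips))
    for nd in active:
        nd.edge.length += final
    for i, nd in enumerate(active, start=1):
        nd.taxon = tns.new_taxon(label=f"T{i}")
    tree.seed_node.edge.length = None
    return tree


# ---------------------------------------------------------------------------
# Comparative study simulation
# ---------------------------------------------------------------------------

def _simulate_traits(species: Sequence[str], rng: np.random.Generator
                     ) -> list[TraitRecord]:
    """Draw the 15 life-history predictors per species.

    Categorical levels are drawn uniformly; continuous predictors from
    plausible ranges (body mass log-normal around 100 g, clutch 2–8 eggs,
    incubation 10–40 d, climate from temperate ranges).  Only the
    statistical structure matters downstream, not ornithological realism.
    """
    records = []
    for sp in species:
        kwargs: dict = {"species": sp}
        kwargs["body_mass_g"] = float(np.exp(rng.normal(np.log(100.0), 1.2)))
        kwargs["clutch_size"] = float(np.round(rng.uniform(2, 8), 1))
        kwargs["incubation_period_d"] = float(np.round(rng.uniform(10, 40), 1))
        kwargs["annual_mean_temp"] = float(np.round(rng.uniform(-5, 28), 2))
        kwargs["annual_mean_precip"] = float(np.round(rng.uniform(100, 3000), 0))
        for name, levels in CATEGORICAL_LEVELS.items():
            kwargs[name] = levels[int(rng.integers(0, len(levels)))]
        records.append(TraitRecord(**kwargs))
    return records


def simulate_study(tree: dendropy.Tree, spec: TraitSimSpec
                   ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a full comparative study on ``tree``.

    Returns ``(trait_table, individual_table, truth)`` where ``trait_table``
    has one row per species (15 predictors), ``individual_table`` one row per
    scan (species, specimen, scan, response) and ``truth`` records the
    generating β, λ and σ values for parameter-recovery tests.
    """
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(tips) < spec.n_species:
        raise ValueError(f"tree has {len(tips)} tips < {spec.n_species} species")
    species = tips[:spec.n_species]
    rng = np.random.default_rng(spec.seed)

    traits = _simulate_traits(species, rng)
    trait_df = pd.DataFrame([{
        "species": t.species,
        **{k: getattr(t, k) for k in ALL_PREDICTORS},
    } for t in traits])

    # fixed effects Xβ
    xb = np.full(spec.n_species, spec.intercept)
    for (pred, level), beta in spec.fixed_effects.items():
        if pred in CATEGORICAL_LEVELS:
            xb += beta * (trait_df[pred].to_numpy() == level)
        else:
            xb += beta * trait_df[pred].to_numpy(dtype=float)

    # phylogenetic effect under the λ transform (C normalized: deepest tip = 1)
    pc = vcv(tree, taxa=species, normalize=True)
    C_lam = lambda_transform(pc.matrix, spec.lam)
    if spec.sigma_phylo > 0:
        L = np.linalg.cholesky(C_lam + 1e-12 * np.eye(spec.n_species))
        u_phylo = spec.sigma_phylo * (L @ rng.standard_normal(spec.n_species))
    else:
        u_phylo = np.zeros(spec.n_species)
    u_species = spec.sigma_species * rng.standard_normal(spec.n_species) \
        if spec.sigma_species > 0 else np.zeros(spec.n_species)
    species_mean = xb + u_phylo + u_species

    lo, hi = spec.specimens_per_species
    n_spec = rng.integers(lo, hi + 1, size=spec.n_species)
    rows = []
    for i, sp in enumerate(species):
        for s in range(int(n_spec[i])):
            for k in range(spec.scans_per_specimen):
                noise = spec.sigma_resid * rng.standard_normal() \
                    if spec.sigma_resid > 0 else 0.0
                rows.append({
                    "species": sp,
                    "specimen": f"{sp}_s{s + 1}",
                    "scan": k + 1,
                    "value": species_mean[i] + noise,
                })
    indiv = pd.DataFrame(rows)
    truth = {
        "intercept": spec.intercept,
        "beta": dict(spec.fixed_effects),
        "lambda": spec.lam,
        "sigma_phylo": spec.sigma_phylo,
        "sigma_species": spec.sigma_species,
        "sigma_resid": spec.sigma_resid,
        "species_mean": pd.Series(species_mean, index=species),
    }
    return trait_df, indiv, truth
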
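# eggsurf

Avian eggshell surfaces differ enormously between species — from near-glassy
bee-eater eggs to hummingbird shells three orders of magnitude rougher — and
that texture mediates microbial defence, wettability and wear in the nest.
`eggsurf` is a reusable pipeline for studying this variation: it quantifies
surface texture from 3-D profilometry height maps and asks, within a
phylogenetically informed framework, which life-history and nest-environment
traits predict it.

The package is aimed at comparative biologists with interferometric scans of
biological surfaces (one height grid per scan, with missing pixels where the
surface left the focal plane) and a species phylogeny with branch lengths.

## What it computes

**Areal texture parameters.** For valid pixels z₁..zₙ with mean z̄:

- Sa = (1/n) Σ|zᵢ − z̄| — arithmetic-mean roughness (nm)
- Sq = √((1/n) Σ(zᵢ − z̄)²) — RMS roughness (nm)
- Ssk = (1/n) Σ(zᵢ − z̄)³ / Sq³ — skewness (< 0: valley-dominated, e.g. porous shell)
- Sku = (1/n) Σ(zᵢ − z̄)⁴ / Sq⁴ — kurtosis (3 = Gaussian reference)

computed after second-order polynomial form correction (the fragment is a
near-spherical cap) with the lowest valid height shifted to exactly 0 nm,
and after a coverage-based QC step that crops low-quality scan borders or
rejects scans below 40% pixel coverage.

**Quality control and aggregation.** Repeatability (one-way random-effects
ICC) of repeated scans per fragment; two-stage averaging (scans → specimen
→ species); Cook's-distance influence filtering of specimen values with
species-level retention rules; response transforms (log₁₀ Sa, Ssk, log₁₀ Sku).

**Comparative analysis.** Pagel's λ by maximum likelihood with
likelihood-ratio tests against λ=0 and λ=1 (χ²₁); PGLS regression;
a pairwise-correlation (< 0.75) + VIF (< 10) predictor screen; and a
Bayesian phylogenetic mixed model (animal model) fitted by a conjugate
Gibbs sampler:

    y = Xβ + a + b + e,  a ~ N(0, σ²_p A),  b ~ N(0, σ²_s I),  e ~ N(0, σ²_e I)

with A the phylogenetic correlation matrix, plus pMCMC, HPD intervals, and
batched posterior prediction over a factorial grid of predictors.

**Synthetic data.** Every stage is testable offline: seeded generators
produce height maps (spherical-cap form + correlated Gaussian field +
pore-like pits + edge-concentrated missing pixels), Yule trees, and trait
datasets under λ-transformed Brownian motion with known fixed effects.

## Worked example

```python
import eggsurf as es

# one synthetic scan with pores and edge dropout, like a real interferometer scan
spec = es.SurfaceSpec(nrow=576, ncol=768, base_radius_um=20000.0,
                      pore_density=2.0, edge_dropout=0.15, seed=42)
raw = es.gen_height_map(spec)
checked = es.assess_and_crop(raw, coverage_threshold=0.40, min_area=10000)
tex = es.compute_texture(es.plane_correct(checked))
print(f"Sa = {tex.sa:.1f} nm, Sq = {tex.sq:.1f} nm, "
      f"Ssk = {tex.ssk:.3f}, Sku = {tex.sku:.3f}, coverage = {tex.coverage:.2f}")

# comparative stage: phylogenetic signal in simulated species means
tree = es.gen_tree(120, seed=7)
sim = es.TraitSimSpec(n_species=120, lam=0.6, seed=11)
traits, indiv, truth = es.simulate_study(tree, sim)
_, species_means = es.aggregate(indiv, ["value"])
pc = es.vcv(tree, taxa=list(species_means["species"]), normalize=True)
fit = es.fit_lambda(species_means["value"].to_numpy(), pc)
print(f"Pagel's lambda = {fit.lam:.2f} (true 0.6), "
      f"p(lambda=0) = {fit.p_lambda0:.2e}, p(lambda=1) = {fit.p_lambda1:.2e}")
```

prints

```
Sa = 43.4 nm, Sq = 56.8 nm, Ssk = -0.663, Sku = 5.072, coverage = 0.85
Pagel's lambda = 0.40 (true 0.6), p(lambda=0) = 3.40e-05, p(lambda=1) = 1.20e-19
```

The scan's negative Ssk reflects its punched pores (valley-dominated
surface) and Sku > 3 their deep, sharp troughs; the signal test finds an
intermediate λ significantly different from both no-signal (λ=0) and pure
Brownian motion (λ=1), as expected for a trait generated at λ=0.6 (a single
120-species realization estimates λ with considerable sampling spread).

A subcommand CLI mirrors the pipeline stages (`eggsurf simulate | texture |
qc | signal | pgls | mcmc | predict`); every command logs its seed and
thresholds, and every output table records the seed and config hash.

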
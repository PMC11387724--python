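# plumagediv

Comparative analysis of plumage-colour divergence between bird species, as
perceived by birds themselves, against three candidate drivers: shared
evolutionary history, geographic co-occurrence, and the light environment of
the habitats the species occupy.

The package is aimed at researchers in avian visual ecology and phylogenetic
comparative methods.  It takes reflectance spectra per species × sex ×
plumage patch, a dated phylogeny, species range polygons, and gridded NDVI /
habitat-suitability surfaces, and produces the pairwise and species-level
regression tables of a colour-divergence study.  A first-class synthetic-data
module generates all of these inputs with known, recoverable statistical
structure, so every stage can be validated without field or museum data.

## The models at the core

**Receptor-noise colour distances.**  Reflectance spectra R(λ) on the 1-nm
300–700 nm grid are converted to quantum catches of the four single cones of
a UV-sensitive (UVS) avian visual system under an idealized flat illuminant,

    qᵢ = Σ_λ R(λ) · I(λ) · Sᵢ(λ),

with Sᵢ(λ) Govardovskii A1 pigment templates (default λmax = 372, 456, 544,
609 nm).  Colour distance between two stimuli uses Fechner signals
Δfᵢ = ln(qᵢᵃ/qᵢᵇ) and channel noise eᵢ = w·√(η_ref/ηᵢ) (default relative
densities 1:2:2:4, Weber fraction w = 0.1 on the most abundant cone):

    ΔS² = Σ_{i<j} (Π_{k≠i,j} e_k)² (Δf_j − Δf_i)²  /  Σ_k (Π_{i≠k} e_i)²

in just-noticeable-difference (JND) units — a distance below 1 is not
discriminable by the modelled viewer.  Per-patch distance matrices over all
species pairs are averaged across the six patches (crown, mantle, throat,
two breast bands, belly) into a whole-body matrix.

**Geography.**  For each species pair: minimal distance between range
polygons, intersection area, and both directional overlap fractions
(intersection divided by each species' range area).  A pair is *sympatric*
iff the intersection has positive area.

**Niche overlap.**  Schoener's D between normalized suitability surfaces,
D = 1 − ½ Σᵢ |pᵢ − qᵢ| ∈ [0, 1], computed for an NDVI-only surface and for a
combined all-variables surface; plus each species' mean NDVI over its range.

**Regressions.**  Colour distance per patch is regressed (GLS, standardized
predictors) on phylogenetic distance, a geographic predictor, and NDVI
overlap, in three partitions: all pairs (geographic predictor = sympatry
indicator), sympatric pairs (overlap fraction), allopatric pairs (minimal
distance).  Species-level colorimetrics — mean brightness B2, peak-wavelength
hue H1, and segment chroma S1 in six bands (U, V, B, G, Y, R) — are
regressed on mean NDVI by PGLS with error covariance σ²·C(λ), both at fixed
λ = 1 and with Pagel's λ estimated by maximum likelihood on [0, 1].  All
p-values are Benjamini–Hochberg corrected within each output table.

## Worked example

Run the full pipeline on a synthetic 30-species system:

```python
from plumagediv import pipeline

cfg = pipeline.merge_config(
    {"synthetic": {"n_species": 30}, "seed": 42, "outdir": "out"}
)
out = pipeline.run_full_analysis(cfg)

pairs = out["pairs_male"]
print(len(pairs), int(pairs.sympatric.sum()))        # 435 135
g = out["gls_male_all"]
print(g[g.patch == "average"][["predictor", "effect_size", "p_value"]])
```

prints (seed 42):

```
    predictor  effect_size      p_value
   phylo_dist     0.649769 2.184433e-12
geo_predictor    -0.205981 5.641670e-01
 ndvi_overlap     0.166991 3.147396e-01
```

Of the 435 species pairs, 135 are sympatric (the generator targets a 0.31
sympatric fraction).  The whole-body colour distance increases significantly
with phylogenetic distance (standardized effect 0.65): in this synthetic
system plumage peaks drift apart by Brownian motion, so older splits look
more different.  Sympatry and NDVI overlap, which do not enter the
generative model for spectra, show no significant effect.  The PGLS table
(`out["pgls_male"]`) reports, e.g. for crown hue H1 against mean NDVI,
estimate −124.1 (p = .0011) at fixed λ = 1 and −87.2 (p = .074) with ML
λ̂ = 0.92.

The same run is available from the shell:

```
plumagediv all --seed 42 --outdir out
```

which writes the pair tables, per-partition GLS tables, PGLS tables, JND
matrices and a manifest sufficient to reproduce the outputs byte-for-byte.

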
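# soilecol

Analysis toolkit for soil bacterial community surveys that combine
culture-based profiling, gel/T-RF community fingerprints and soil carbon
chemistry — the kind of balanced land-use × season field campaign used to ask
whether agricultural management reshapes the soil microbiota.

It is aimed at soil microbiologists and biogeochemists who have:

- **colony counts by appearance day** from dilution plating (days 1, 2, 6),
- **densitometric lane traces or band tables** from DGGE gels or T-RFLP runs,
- **cumulative CO₂ respiration series** from incubation experiments,
- **carbon fractionation records** (C_org, C_ext, C_HA+FA, C_mic),

and want the standard derived indicators, their statistics and the
multivariate synthesis in one tested, scriptable package.

## What it computes

**Ecophysiology.** CFU g⁻¹, the r/K strategist split (colonies within 48 h are
r-strategists) and the eco-physiological index

EP = −Σᵢ Pᵢ ln Pᵢ,

the entropy of the colony appearance-day distribution (EP = 0 when one class
holds every colony, ln 3 at even thirds). Land-use, season and interaction
effects are tested with a balanced two-way fixed-effects ANOVA (logit and log
transforms provided).

**Fingerprints.** Rolling-ball background subtraction, band calling with a
minimum-slope criterion and a 2 %-of-maximum cutoff, cross-lane band matching
into classes, richness R, Shannon H′ = −Σ Pᵢ ln Pᵢ, Simpson dominance
D = Σ Pᵢ², Pielou evenness J = H′/ln R, and pairwise Dice, Jaccard and
Bray-Curtis (1 − 2C_ij/(S_i+S_j)) measures.

**Clustering & ordination.** UPGMA with a deterministic tie rule, cophenetic
correlation, Newick export, k-cluster tree cuts, group averaging with min–max
normalization for heat-map tables, and PCA (covariance or correlation based)
with percent-variance reporting.

**Soil carbon.** SOM = 1.724 C_org, the humification indicators HI, DH %,
HR %, nonlinear least-squares fitting of first-order mineralization
C_m(t) = C₀(1 − e^(−kt)), and the microbial quotients C_cum, C_bas,
qCO₂ = C_bas/C_mic, qM and C_mic:C_org.

**Synthetic data.** A generator that emulates the balanced 5 land-use ×
2 season × 5 replicate study design with controllable group effects, so every
stage is testable end to end with known ground truth.

## Worked example

```python
from soilecol import ColonyCounts, cfu_per_gram, ep_index

plate = ColonyCounts({1: 60, 2: 45, 6: 25}, dilution_exponent=4)
res = ep_index(plate)
print(f"CFU per g soil : {cfu_per_gram(plate):.3e}")
print(f"r-strategists  : {res.r_percent:.1f}%")
print(f"EP index       : {res.ep:.4f} nats")
```

prints

```
CFU per g soil : 1.300e+08
r-strategists  : 80.8%
EP index       : 1.0411 nats
```

130 colonies on a 10⁻⁴ plate of a 1 g / 10 ml suspension give 1.3×10⁸ CFU g⁻¹;
80.8 % of colonies appeared within 48 h (r-strategists), and the EP index of
1.04 (close to the ln 3 ≈ 1.10 maximum) indicates an even spread over
growth-rate guilds. The full simulated study runs in one call:

```bash
python examples/05_full_pipeline.py
```

```
samples analysed      : 50
EP ~ land use         : F = 29.59, p = 1.78e-11
EP ~ land use x season: F = 3.33, p = 0.019
cophenetic correlation: 0.613
group PCA             : PC1 = 49.96%, PC2 = 24.65% of variance
```

i.e. on the default synthetic study the land-use effect on EP is strong, the
land-use × season interaction is detectable, and the first two components of
the group-level parameter table carry ~75 % of the variance. The other
`examples/*.py` scripts walk through each capability separately, and the
`soilecol` command exposes the stages as subcommands
(`simulate`, `ecophys`, `fingerprint`, `cluster`, `soilcarbon`, `report`,
`run-all`).

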
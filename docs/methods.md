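# Methods

## Study design and scope

The package models a balanced field survey: five land-use types of increasing
management intensity (cork-oak forest CO, hayland-pasture rotation PA, managed
meadow MM, grass-covered vineyard CV, tilled vineyard TV), each sampled in
spring and autumn with the same number of field replicates (default 5, i.e.
50 samples). All analyses assume this balanced two-factor layout; unbalanced
inputs are rejected explicitly rather than silently re-weighted.

Wet-lab steps (soil handling, DNA extraction, electrophoresis, titrations) and
taxonomic assignment of sequences are out of scope: inputs begin at colony
counts, 1-D densitometric traces or pre-called band tables, cumulative CO₂
series and carbon fraction records.

## Ecophysiological profiling

Colonies are classed by first appearance on days 1, 2 and 6 of incubation.
CFU g⁻¹ = total × 10^dilution × (suspension volume / plated volume) / soil
mass; the conventional 30–300 colony validity window is enforced as a warning
so synthetic extremes remain analysable. Colonies within 48 h are
r-strategists; the EP index is the Shannon entropy of the three class
proportions with 0·log 0 ≡ 0.

*Log base.* The entropy-style EP and H′ formulas do not fix a base; the
package defaults to natural log (values in nats, maximum ln 3 ≈ 1.0986 for
three classes) with `base=10` available — reported values should state the
base.

*Logit transform.* ln(p/(1−p)) for proportions; exact 0/1 is a domain error by
default, with an opt-in empirical shrink p ← (p(n−1)+0.5)/n for boundary
values. No silent correction is applied.

*ANOVA.* Classical balanced fixed-effects two-way decomposition
(SS_A + SS_B + SS_AB + SS_res = SS_total exactly on balanced data), F tests
against the residual mean square; ≥ 2 replicates per cell are required for the
interaction. Zero-variance data yield NaN F statistics flagged to the caller.
Restricting to balanced designs avoids the Type I/II/III sums-of-squares
ambiguity entirely. Post-hoc pairwise procedures are deliberately not
provided.

## Fingerprint processing

Traces are assumed aligned to a common relative-migration (Rf ∈ [0,1]) axis by
reference marker lanes upstream; gel-to-gel alignment is not reimplemented.

1. **Background**: morphological rolling-ball subtraction
   (`skimage.restoration.rolling_ball`, default radius 50 grid units), output
   clamped at zero. A constant trace maps to zero; narrow peaks are preserved
   because the ball cannot follow them.
2. **Band calling**: moving-average smoothing (window 3 grid units by
   default — the commercial tools' "noise reduction" parameter has no
   documented meaning, so a plain smoother with an explicit window is used),
   local maxima via `scipy.signal.find_peaks`, a minimum steepest-rising-edge
   slope criterion, and removal of peaks below 2 % of the tallest retained
   peak. `min_slope` is in intensity per grid unit on the smoothed trace: it
   is meaningful only relative to the trace's intensity scaling. The carried
   default of 200 suits high-dynamic-range scanner output; for the synthetic
   traces used in the tests (heights in the hundreds, ~1000-point grids) an
   explicit `min_slope=1.0` is the appropriate scale.
3. **Matching**: pooled band positions are sorted and split where the gap
   exceeds the tolerance — in one dimension this equals the transitive closure
   of the "within tolerance" relation (single linkage). A lane contributing
   two bands to one class keeps the band nearer the class centroid, ties
   resolved toward smaller Rf; the procedure is deterministic and order
   independent.

*Intensity basis.* Band abundance may be taken from peak height or peak area;
height is the default and the choice is a recorded config field, since the two
conventions coexist in practice.

Diversity indices treat each band class as one OTU. Dice and Jaccard operate
on presence/absence, Bray-Curtis on abundances; both-empty pairs are defined
as similarity 1 (distance 0) so degenerate lanes do not crash a matrix build.

## Clustering, heat map and PCA

UPGMA is implemented directly (size-weighted average linkage) with a
lexicographic tie rule on cluster leaf sets, making merges reproducible across
platforms; scipy's average linkage serves as an independent cross-check in the
test suite, not as the implementation. Cophenetic correlation is the Pearson
correlation between original and first-common-merge distances; it is 1 exactly
when the input is already ultrametric.

The heat-map pipeline is fixed as: group means over (land use, season) →
per-parameter min–max normalization to [0,1] → Bray-Curtis distances → UPGMA.
Normalizing before averaging is available behind a flag
(`normalize_before_average`) but is not the default. A constant parameter is
emitted as all-0.5 with a warning.

PCA is computed by SVD of column-centered data; with `standardize=True`
(default) variables are scaled by their sample standard deviation, i.e. the
correlation matrix is decomposed — the appropriate choice when chemical
(% of dry soil) and biochemical (mg kg⁻¹, day⁻¹) variables share one table.
Component signs are fixed so each loading column's largest-magnitude entry is
positive. Variance percentages come from the squared singular values and sum
to 100.

Newick export uses the ultrametric convention: node height = merge distance/2,
leaf height 0, branch length = parent height − child height, so leaf-to-leaf
path lengths equal cophenetic distances. Output round-trips through dendropy.

## Soil carbon

SOM = 1.724 × C_org (van Bemmelen). From the fractionation C_org ≥ C_ext ≥
C_HA+FA ≥ 0: C_NH = C_ext − C_HA+FA, HI = C_NH/C_HA+FA, DH % = 100
C_HA+FA/C_ext, HR % = 100 C_HA+FA/C_org. These are the standard
Ciavatta/Sequi-style definitions; each output table records them explicitly.
HI with a zero humified fraction is NaN, flagged, never silently zero.

Mineralization kinetics C_m(t) = C₀(1 − e^(−kt)) are fitted by bounded
trust-region nonlinear least squares (`scipy.optimize.least_squares`),
initialized at C₀ = 1.1 × max(C_m) and k from a through-origin log-linear
regression of log(1 − C_m/C₀_init) on t; termination at relative parameter
change < 1e-8 or 500 residual evaluations, with convergence flagged in the
result. The model passes through the origin, so no artificial (0,0) point is
added. k̂ is invariant to rescaling C_m; Ĉ₀ scales proportionally.

C_cum is the cumulative CO₂-C at day 28. C_bas is the mean daily rate over the
final measured interval (days 21–28 on the standard 1, 2, 4, 7, 10, 14, 21,
28 schedule): with discrete trapping days a literal single-day value at day 28
is unobservable, so the interval mean is the defensible estimator. qCO₂ =
C_bas/C_mic is reported per day (the incubation's native resolution; per-hour
is a unit conversion away); qM = C_cum/C_org and C_mic:C_org convert C_org
from % to mg kg⁻¹ (× 10⁴) so numerator and denominator share units.

## Synthetic generator

The generator's defaults define the study conditions used throughout the
tests:

- **Design**: 5 × 2 × 5 balanced, 50 samples.
- **Colony counts**: lognormal plate totals (mean 150, dispersion σ = 0.2,
  multiplicative noise keeps counts positive) split multinomially over the
  group's day-class proportions. Default proportions make r-strategists
  dominant everywhere, give MM the most uneven distribution (lowest EP) and
  TV the largest seasonal shift — the qualitative pattern such surveys report.
- **Band communities**: a shared pool of 40 species at fixed Rf positions,
  partitioned into a ubiquitous core (occupancy 0.9), season-indicator blocks
  and land-use-indicator blocks whose occupancy contrast is scaled by
  `season_effect` and `land_use_effect` in [0,1] (defaults 0.8 and 0.6;
  1.0 makes indicators nearly exclusive, 0 removes all group structure).
  Abundances are lognormal around a species-level mean (~10³).
- **Respiration**: exact first-order curves plus i.i.d. Gaussian noise
  (default SD 10 mg C kg⁻¹), clipped at zero, optionally re-monotonized.
  Group C₀ values (400–850 mg C kg⁻¹) decline from spring to autumn and are
  highest under forest; k spans 0.038–0.05 day⁻¹.
- **Chemistry**: C_org lognormal around group means (CV 0.1 by default); the
  extractable and humified pools are generated as noisy ratios of the level
  above, so the ordering C_HA+FA ≤ C_ext ≤ C_org and the identity
  C_NH = C_ext − C_HA+FA hold by construction in every record.
- **Seeding**: one global seed expands into per-stream seeds by fixed offsets,
  so stages are independently reproducible; identical seeds give bit-identical
  outputs.

Replicate variance components are not reported for such field studies, so the
noise levels above are realistic choices, not calibrated constants.

*What the generator does not emulate*: spatial autocorrelation among field
replicates, gel-to-gel migration distortion (inputs are already in common Rf
coordinates), co-migrating distinct sequences in one band, detection
saturation of dense lanes, seasonal autocorrelation within a plot, or
measurement error correlated across chemistry variables. Passing tests
therefore demonstrate correctness of the computations and recoverability of
planted group structure — not that real gels or titrations behave this
benignly.

## Problem sizes and numerical conventions

The test and reproduction runs use the study-scale design (50 samples),
2000 null simulations for ANOVA calibration, 100–200 Monte-Carlo replicates
for power and kinetics recovery, and ≤ 8-leaf random instances for the
oracle-equivalence checks — sizes at which the Monte-Carlo error bands quoted
in the tests (3 SE) are meaningful.

Ties in UPGMA are broken lexicographically; band-class ties toward smaller Rf;
PCA signs by the largest-magnitude loading; 0·log 0 ≡ 0 throughout; distances
must be symmetric with an exactly zero diagonal; NaN inputs are rejected, not
propagated.

## Known limitations

- The published study's measured chemistry/biochemistry tables are available
  only as word-processor supplements, so the package cannot re-derive the
  printed PCA variance figures (PC1 = 44.59 %, PC2 = 24.47 %) from
  distributed data; the corresponding check is recorded as failing until the
  supplement is transcribed (both replicate-row and group-mean-row PCA modes
  should then be tried).
- Post-hoc pairwise contrasts after ANOVA are not implemented (no procedure is
  standard for these surveys).
- T-RF peak tables are accepted as given; upstream capillary-specific
  filtering is not reimplemented.
- Dendrogram bootstrap support is not provided; tree confidence is summarized
  by the cophenetic correlation only.
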